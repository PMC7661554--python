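"""Readers, validators and writers for every external table and sequence
file the pipeline consumes, plus the bin quality filter.

All tabular inputs are plain TSV; genome bins arrive as FASTA (or a
contig-length table), gene calls as GFF3 (or a gene table). Homology hits
use the de facto 12-column tabular search format (query, subject, identity,
alignment length, mismatches, gaps, qstart, qend, sstart, send, e-value,
bitscore). Every reader takes ``strict=True`` (raise on malformed rows,
naming the line) or ``strict=False`` (skip malformed rows with a logged
count).

Bin QC follows single-copy-marker quality estimates: bins are retained when
completeness is strictly above 80% and contamination strictly below 5%
(both configurable).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .homology import HomologyHit

log = logging.getLogger(__name__)


class TableParseError(ValueError):
    """Malformed input row; message names the file and line number."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


HITS_COLUMNS = (
    "query_id", "subject_id", "identity", "aln_length", "mismatches",
    "gaps", "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass
class GenomeBin:
    """A metagenome-assembled genome: contigs, genes and QC metrics."""

    bin_id: str
    contigs: list[tuple[str, int]]
    genes: list[str] = field(default_factory=list)
    completeness: float | None = None
    contamination: float | None = None

    def __post_init__(self) -> None:
        for contig_id, length in self.contigs:
            if length <= 0:
                raise ValidationError(
                    f"bin {self.bin_id}: contig {contig_id} has non-positive "
                    f"length {length}"
                )
        for metric, name in ((self.completeness, "completeness"),
                             (self.contamination, "contamination")):
            if metric is not None and not 0.0 <= metric <= 100.0:
                raise ValidationError(
                    f"bin {self.bin_id}: {name} {metric} outside [0, 100]"
                )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"bin {self.bin_id}: duplicate gene ids")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.contigs)

    @property
    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.contigs]


@dataclass(frozen=True)
class GeneRecord:
    """A called gene located on one contig of one bin.

    Coordinates follow the GFF3 convention: 1-based, inclusive.
    ``product_labels`` collects the category labels attached downstream
    (peptidase family, Pfam accession, pathway gene symbol, ...).
    """

    gene_id: str
    bin_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    signal_peptide: bool = False
    product_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: bad strand {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ContigDepthRecord:
    """Mean read depth of one contig in one sample."""

    sample_id: str
    contig_id: str
    length: int
    mean_depth: float

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValidationError(
                f"contig {self.contig_id} in sample {self.sample_id}: "
                f"negative depth {self.mean_depth}"
            )


# ---------------------------------------------------------------------------
# readers

def _read_tsv(path: str | os.PathLike, columns: Sequence[str],
              dtypes: Mapping[str, type] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing columns {missing}")
    if dtypes:
        try:
            df = df.astype(dtypes)
        except (ValueError, TypeError) as exc:
            raise TableParseError(f"{path}: bad value types ({exc})") from exc
    return df


def parse_hits_table(
    path: str | os.PathLike,
    query_lengths: Mapping[str, int] | None = None,
    strict: bool = True,
) -> list[HomologyHit]:
    """Parse a 12-column tabular homology search file into hits.

    Query coverage is ``aln_length / query_length * 100`` when
    ``query_lengths`` (in the same residue unit as aln_length) is supplied,
    else flagged unavailable (``coverage=None``) with one warning.
    """
    hits: list[HomologyHit] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                if strict:
                    raise TableParseError(
                        f"{path}: line {lineno}: expected 12 tab-separated "
                        f"columns, got {len(fields)}"
                    )
                n_bad += 1
                continue
            try:
                identity = float(fields[2])
                aln_length = int(fields[3])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                if strict:
                    raise TableParseError(
                        f"{path}: line {lineno}: {exc}"
                    ) from exc
                n_bad += 1
                continue
            coverage = None
            if query_lengths is not None:
                qlen = query_lengths.get(fields[0])
                if qlen:
                    coverage = min(100.0, 100.0 * aln_length / qlen)
            try:
                hits.append(
                    HomologyHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        identity=identity,
                        coverage=coverage,
                        bitscore=bitscore,
                        evalue=evalue,
                        aln_length=aln_length,
                    )
                )
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
    if n_bad:
        log.warning("%s: skipped %d malformed rows (lenient mode)", path, n_bad)
    if query_lengths is None and hits:
        log.warning(
            "%s: no query-length table; query coverage unavailable", path
        )
    return hits


def read_qc_table(path: str | os.PathLike) -> pd.DataFrame:
    """QC table: bin_id, completeness, contamination."""
    df = _read_tsv(path, ("bin_id", "completeness", "contamination"),
                   {"completeness": float, "contamination": float})
    for _, row in df.iterrows():
        if pd.isna(row.completeness) or pd.isna(row.contamination):
            raise ValidationError(
                f"bin {row.bin_id}: missing QC metric"
            )
    return df


def read_contig_table(path: str | os.PathLike) -> pd.DataFrame:
    """Contig table: contig_id, bin_id, length (bp)."""
    return _read_tsv(path, ("contig_id", "bin_id", "length"),
                     {"length": int})


def read_bins_fasta(
    paths: Mapping[str, str | os.PathLike],
) -> dict[str, list[tuple[str, int]]]:
    """Read one FASTA per bin; returns bin_id -> [(contig_id, length)]."""
    out: dict[str, list[tuple[str, int]]] = {}
    for bin_id, path in paths.items():
        out[bin_id] = [
            (rec.id, len(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
        ]
        if not out[bin_id]:
            raise ValidationError(f"bin {bin_id}: empty FASTA {path}")
    return out


def read_gene_table(path: str | os.PathLike) -> list[GeneRecord]:
    """Gene table: gene_id, bin_id, contig_id, start, end, strand."""
    df = _read_tsv(path, ("gene_id", "bin_id", "contig_id",
                          "start", "end", "strand"),
                   {"start": int, "end": int})
    records = [
        GeneRecord(
            gene_id=row.gene_id, bin_id=row.bin_id, contig_id=row.contig_id,
            start=int(row.start), end=int(row.end), strand=row.strand,
        )
        for row in df.itertuples()
    ]
    _check_unique_genes(records)
    return records


def read_genes_gff3(
    path: str | os.PathLike,
    contig_to_bin: Mapping[str, str],
    feature_type: str = "CDS",
) -> list[GeneRecord]:
    """Read gene calls from GFF3; bin membership via the contig map."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    records = []
    for feat in db.features_of_type(feature_type, order_by="start"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        bin_id = contig_to_bin.get(feat.seqid)
        if bin_id is None:
            raise ValidationError(
                f"{path}: contig {feat.seqid} (gene {gene_id}) not in any bin"
            )
        records.append(
            GeneRecord(
                gene_id=gene_id, bin_id=bin_id, contig_id=feat.seqid,
                start=feat.start, end=feat.end, strand=feat.strand,
            )
        )
    _check_unique_genes(records)
    return records


def _check_unique_genes(records: Sequence[GeneRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValidationError(f"duplicate gene id {rec.gene_id}")
        seen.add(rec.gene_id)


def read_depth_table(path: str | os.PathLike) -> pd.DataFrame:
    """Depth table: sample_id, contig_id, length, mean_depth."""
    df = _read_tsv(path, ("sample_id", "contig_id", "length", "mean_depth"),
                   {"length": int, "mean_depth": float})
    if (df.mean_depth < 0).any():
        bad = df.loc[df.mean_depth < 0].iloc[0]
        raise ValidationError(
            f"contig {bad.contig_id} in sample {bad.sample_id}: negative depth"
        )
    return df


def read_count_table(path: str | os.PathLike) -> pd.DataFrame:
    """Count table: sample_id, gene_id, count (reads)."""
    df = _read_tsv(path, ("sample_id", "gene_id", "count"), {"count": int})
    if (df["count"] < 0).any():
        raise ValidationError(f"{path}: negative read count")
    return df


def read_signal_table(path: str | os.PathLike) -> dict[str, bool]:
    """Signal-peptide calls: gene_id, call in {SP, OTHER} -> bool map."""
    df = _read_tsv(path, ("gene_id", "call"))
    bad = set(df.call.unique()) - {"SP", "OTHER"}
    if bad:
        raise ValidationError(f"{path}: unknown signal calls {sorted(bad)}")
    return dict(zip(df.gene_id, df.call == "SP"))


def read_reference_map(path: str | os.PathLike) -> dict[str, tuple[str, str]]:
    """Reference map: subject_id, category_kind, category_label.

    A subject listed twice with conflicting kind/label is an error.
    """
    df = _read_tsv(path, ("subject_id", "category_kind", "category_label"))
    out: dict[str, tuple[str, str]] = {}
    for row in df.itertuples():
        entry = (row.category_kind, row.category_label)
        if row.subject_id in out and out[row.subject_id] != entry:
            raise ValidationError(
                f"{path}: subject {row.subject_id} mapped to conflicting "
                f"labels {out[row.subject_id]} and {entry}"
            )
        out[row.subject_id] = entry
    return out


def read_substrate_map(path: str | os.PathLike) -> dict[str, str]:
    """Substrate map: aa, sample_id — which culture was fed which amino acid."""
    df = _read_tsv(path, ("aa", "sample_id"))
    if df.aa.duplicated().any():
        raise ValidationError(f"{path}: amino acid mapped to several samples")
    return dict(zip(df.aa, df.sample_id))


def read_identity_table(path: str | os.PathLike,
                        value_col: str = "identity") -> pd.DataFrame:
    """Pairwise identity table: query_id, reference_id, <value_col> (%)."""
    df = _read_tsv(path, ("query_id", "reference_id", value_col),
                   {value_col: float})
    out_of_range = ~df[value_col].between(0, 100)
    if out_of_range.any():
        raise ValidationError(f"{path}: {value_col} outside [0, 100]")
    return df


def read_label_table(path: str | os.PathLike) -> dict[str, str]:
    """Reference label table: reference_id, cluster_label."""
    df = _read_tsv(path, ("reference_id", "cluster_label"))
    return dict(zip(df.reference_id, df.cluster_label))


# ---------------------------------------------------------------------------
# bin QC filter

def qc_filter_bins(
    bins: Sequence[GenomeBin],
    min_completeness: float = 80.0,
    max_contamination: float = 5.0,
) -> list[GenomeBin]:
    """Retain bins with completeness > ``min_completeness`` and
    contamination < ``max_contamination`` (both strict), preserving order."""
    kept = []
    for b in bins:
        if b.completeness is None or b.contamination is None:
            raise ValidationError(f"bin {b.bin_id}: missing QC metric")
        if b.completeness > min_completeness and b.contamination < max_contamination:
            kept.append(b)
    return kept


def bins_from_tables(qc: pd.DataFrame, contigs: pd.DataFrame,
                     genes: Sequence[GeneRecord] = ()) -> list[GenomeBin]:
    """Assemble GenomeBin objects from the QC and contig tables."""
    contig_groups = {
        bin_id: list(zip(grp.contig_id, grp.length))
        for bin_id, grp in contigs.groupby("bin_id", sort=False)
    }
    gene_groups: dict[str, list[str]] = {}
    for rec in genes:
        gene_groups.setdefault(rec.bin_id, []).append(rec.gene_id)
    bins = []
    for row in qc.itertuples():
        bins.append(
            GenomeBin(
                bin_id=row.bin_id,
                contigs=contig_groups.get(row.bin_id, []),
                genes=gene_groups.get(row.bin_id, []),
                completeness=float(row.completeness),
                contamination=float(row.contamination),
            )
        )
    return bins


# ---------------------------------------------------------------------------
# report writing

def write_report(tables: Mapping[str, pd.DataFrame],
                 out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write each named table as ``<name>.tsv`` with a header row.

    Returns the manifest (file, n_rows), itself written as manifest.tsv.
    Column order is preserved as given, so writes are deterministic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, df in tables.items():
        fname = f"{name}.tsv"
        df.to_csv(out / fname, sep="\t", index=False, float_format="%.6g")
        entries.append({"file": fname, "n_rows": len(df)})
    manifest = pd.DataFrame(entries, columns=["file", "n_rows"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
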