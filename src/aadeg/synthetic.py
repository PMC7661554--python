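"""Seeded generator of a mock amino-acid enrichment community with known
ground truth.

The generator emulates the study design the pipeline targets: a set of
genome bins with planted relative abundances, functional gene inventories
(peptidases by catalytic type, secreted enzymes, adhesion domains, SusC
transporters, electron-transfer markers), planted amino-acid pathway
inventories (complete, or missing the first *k* genes of a route), and one
enrichment culture per amino-acid substrate. It emits exactly the table
dialects the readers consume — QC, contigs, genes, 12-column homology hits,
signal-peptide calls, per-sample depth and count tables, substrate map,
16S/AAI/SusC identity tables — plus a structured ground-truth record.

Noise model: read counts per contig and per gene are Poisson with mean
proportional to planted abundance x sample depth (x gene length for
counts); with ``noise=False`` every value equals its expectation, so every
pipeline estimate must recover its planted value exactly. Gene sequences
are not generated; hit tables are synthesized directly with identities
drawn above (planted) or below (decoy) the 50% homology filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import ValidationError
from .pathway_scoring import AMINO_ACIDS, PathwayDef, load_catalog

# label pools for synthesized category genes
PEPTIDASE_FAMILIES = {
    "M": ("M01", "M03A", "M16B", "M20A", "M23B", "M28A"),
    "S": ("S01A", "S08A", "S09X", "S33", "S41B", "S45"),
    "C": ("C01A", "C02A", "C10", "C25", "C56"),
    "other": ("A08", "T01A", "U32"),
}
LIPASE_FAMILIES = ("abH04", "abH15", "abH23")
GH_FAMILIES = ("GH3", "GH13", "GH23", "GH57")
CAZYME_OTHER = ("PL1", "CE4", "GT2")
ADHESION_DEFAULT = ("PF01103", "PF00754", "PF02494", "PF02496")
ELECTRON_DEFAULT = ("Hyd", "Fdh", "Rnf", "QFR", "NQR")


@dataclass
class PathwayPlan:
    """Planting instruction for one amino acid in one bin.

    ``missing``: number of leading route genes omitted (0 = complete).
    ``expressed`` applies only to complete routes: True plants every route
    gene active in the culture fed this amino acid, False silences them all
    there.
    """

    route: str | None = None
    missing: int = 0
    expressed: bool = False


@dataclass
class BinSpec:
    bin_id: str
    abundance: float
    completeness: float = 95.0
    contamination: float = 1.0
    n_contigs: int = 20
    contig_length_range: tuple[int, int] = (10_000, 40_000)
    pathways: dict[str, PathwayPlan] = field(default_factory=dict)
    extra_symbols: tuple[str, ...] = ()
    peptidases_by_type: dict[str, int] = field(default_factory=dict)
    secreted_peptidases: int = 0
    lipases: int = 0
    secreted_lipases: int = 0
    cazymes_gh: int = 0
    cazymes_other: int = 0
    secreted_cazymes: int = 0
    adhesion: dict[str, int] = field(default_factory=dict)
    susc_polypeptide: int = 0
    susc_glucan: int = 0
    electron_markers: tuple[str, ...] = ()
    n_high_expressed_secreted: int = 0
    n_filler: int = 30
    ssu_best_identity: float | None = None
    aai_best: float | None = None


@dataclass
class CommunitySpec:
    """Study conditions for one synthetic community."""

    bins: list[BinSpec]
    qc_fail_bins: list[BinSpec] = field(default_factory=list)
    substrates: tuple[str, ...] = AMINO_ACIDS
    mean_depth: float = 20.0
    read_length: int = 150
    noise: bool = True
    seed: int = 0
    expr_level: float = 5.0
    high_level: float = 12.0
    baseline_level: float = 1.0

    def __post_init__(self) -> None:
        total = sum(b.abundance for b in self.bins)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"planted abundances sum to {total}, expected 1"
            )
        ids = [b.bin_id for b in self.bins + self.qc_fail_bins]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate bin ids in community spec")

    @property
    def community_depth(self) -> float:
        return self.mean_depth * len(self.bins)


@dataclass
class SyntheticCommunity:
    """All generated tables plus the ground-truth record."""

    spec: CommunitySpec
    qc: pd.DataFrame
    contigs: pd.DataFrame
    genes: pd.DataFrame
    hits: pd.DataFrame
    query_lengths: pd.DataFrame
    reference_map: pd.DataFrame
    signal: pd.DataFrame
    depth: pd.DataFrame
    counts: pd.DataFrame
    substrate_map: pd.DataFrame
    ssu_identity: pd.DataFrame
    aai_identity: pd.DataFrame
    susc_identity: pd.DataFrame
    susc_labels: pd.DataFrame
    truth: dict

    def write(self, out_dir: str | Path, write_fasta: bool = False,
              write_gff: bool = False, seed: int | None = None) -> dict:
        """Write every table as TSV (ground truth as JSON); returns the
        path map. FASTA/GFF3 renditions of contigs and genes are optional
        (sequences are random and carry no planted information)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}
        for name in ("qc", "contigs", "genes", "hits", "query_lengths",
                     "reference_map", "signal", "depth", "counts",
                     "substrate_map", "ssu_identity", "aai_identity",
                     "susc_identity", "susc_labels"):
            df: pd.DataFrame = getattr(self, name)
            p = out / f"{name}.tsv"
            if name == "hits":
                df.to_csv(p, sep="\t", index=False, header=False,
                          float_format="%.6g")
            else:
                df.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths[name] = str(p)
        truth_path = out / "ground_truth.json"
        truth_path.write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        paths["ground_truth"] = str(truth_path)
        if write_gff:
            paths["gff"] = str(self._write_gff(out / "genes.gff3"))
        if write_fasta:
            paths["fasta"] = str(self._write_fasta(out / "contigs.fasta",
                                                   seed=seed))
        return paths

    def _write_gff(self, path: Path) -> Path:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in self.genes.itertuples():
                fh.write(
                    f"{row.contig_id}\taadeg_synthetic\tCDS\t{row.start}\t"
                    f"{row.end}\t.\t{row.strand}\t0\tID={row.gene_id}\n"
                )
        return path

    def _write_fasta(self, path: Path, seed: int | None = None) -> Path:
        rng = np.random.default_rng(self.spec.seed if seed is None else seed)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        with open(path, "w") as fh:
            for row in self.contigs.itertuples():
                seq = rng.integers(0, 4, int(row.length))
                fh.write(f">{row.contig_id}\n")
                s = b"".join(bases[seq]).decode()
                for i in range(0, len(s), 80):
                    fh.write(s[i:i + 80] + "\n")
        return path

    @property
    def gene_lengths_bp(self) -> dict[str, int]:
        return {
            row.gene_id: int(row.end) - int(row.start) + 1
            for row in self.genes.itertuples()
        }


# ---------------------------------------------------------------------------
# generation

def _route_for(catalog: Sequence[PathwayDef], aa: str,
               route: str | None) -> PathwayDef:
    candidates = [p for p in catalog if p.aa == aa]
    if not candidates:
        raise ValidationError(f"no catalog route for amino acid {aa!r}")
    if route is None:
        return candidates[0]
    for p in candidates:
        if p.pathway_id == route:
            return p
    raise ValidationError(f"unknown route {route!r} for {aa!r}")


def _planted_symbols(spec: BinSpec,
                     catalog: Sequence[PathwayDef]) -> set[str]:
    symbols: set[str] = set(spec.extra_symbols)
    for aa, plan in spec.pathways.items():
        route = _route_for(catalog, aa, plan.route)
        if plan.missing >= len(route.genes):
            continue
        symbols.update(route.genes[plan.missing:])
    return symbols


def _truth_encoded(symbols: set[str],
                   catalog: Sequence[PathwayDef]) -> dict[str, bool]:
    # direct catalog walk over the planted symbol set (what the pipeline
    # must recover through the hits -> filter -> assignment chain)
    encoded: dict[str, bool] = {p.aa: False for p in catalog}
    for p in catalog:
        if all(g in symbols for g in p.genes):
            encoded[p.aa] = True
    return encoded


def generate_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Generate all pipeline inputs and the ground truth for one spec.

    Deterministic: the same spec (including its seed) yields identical
    tables, byte for byte once written.
    """
    rng = np.random.default_rng(spec.seed)
    catalog = load_catalog()

    all_bins = list(spec.bins) + list(spec.qc_fail_bins)
    substrate_samples = {aa: f"S_{aa}" for aa in spec.substrates}

    qc_rows, contig_rows, gene_rows = [], [], []
    hit_rows, qlen_rows, signal_rows = [], [], []
    refmap: dict[str, tuple[str, str]] = {}
    # per-gene expression levels: gene_id -> baseline; overrides per sample
    baseline: dict[str, float] = {}
    override: dict[tuple[str, str], float] = {}  # (sample_id, gene_id) -> level
    gene_bp: dict[str, int] = {}
    gene_bin: dict[str, str] = {}

    truth: dict = {
        "abundances": {b.bin_id: b.abundance for b in spec.bins},
        "retained_bins": [b.bin_id for b in spec.bins],
        "qc_fail_bins": [b.bin_id for b in spec.qc_fail_bins],
        "encoded_aa": {}, "expressed_aa": {},
        "encoded_detail": {}, "expressed_detail": {},
        "category_counts": {},
        "pathway_gene_expression": [],
        "susc_clusters": {},
        "ssu_best_identity": {}, "aai_best": {},
        "tau": 0.0,
    }

    def add_hit(gene_id: str, aa_len: int, kind: str, label: str,
                planted: bool = True, low_coverage: bool = False) -> None:
        subject = f"{kind}|{label}"
        if planted:
            refmap[subject] = (kind, label)
            identity = rng.uniform(60.0, 95.0)
            frac = rng.uniform(0.2, 0.45) if low_coverage \
                else rng.uniform(0.75, 0.98)
        else:
            # decoy: fails the identity filter; subject left unmapped half
            # the time to exercise unmapped-subject dropping
            identity = rng.uniform(20.0, 45.0)
            frac = rng.uniform(0.55, 0.95)
            if rng.random() < 0.5:
                refmap.setdefault(subject, (kind, label))
        aln = max(30, int(aa_len * frac))
        bitscore = round(2.0 * aln * identity / 100.0, 1)
        hit_rows.append((gene_id, subject, round(identity, 1), aln, 0, 0,
                         1, aln, 1, aln, 1e-30, bitscore))

    for b in all_bins:
        retained = b in spec.bins
        qc_rows.append({"bin_id": b.bin_id, "completeness": b.completeness,
                        "contamination": b.contamination})
        # --- gene roster: (role, kind, label, secreted, symbol)
        roster: list[tuple[str, str | None, str | None, bool]] = []
        symbols = sorted(_planted_symbols(b, catalog))
        for sym in symbols:
            roster.append((f"pw:{sym}", "pathway_gene", sym, False))
        for ptype, n in sorted(b.peptidases_by_type.items()):
            pool = PEPTIDASE_FAMILIES[ptype]
            for i in range(n):
                roster.append((f"pep:{ptype}:{i}", "peptidase",
                               pool[i % len(pool)], False))
        for i in range(b.lipases):
            roster.append((f"lip:{i}", "lipase",
                           LIPASE_FAMILIES[i % len(LIPASE_FAMILIES)], False))
        for i in range(b.cazymes_gh):
            roster.append((f"caz:gh:{i}", "cazyme",
                           GH_FAMILIES[i % len(GH_FAMILIES)], False))
        for i in range(b.cazymes_other):
            roster.append((f"caz:o:{i}", "cazyme",
                           CAZYME_OTHER[i % len(CAZYME_OTHER)], False))
        for accession, n in sorted(b.adhesion.items()):
            for i in range(n):
                roster.append((f"adh:{accession}:{i}", "adhesion",
                               accession, False))
        for i in range(b.susc_polypeptide + b.susc_glucan):
            roster.append((f"susc:{i}", "transporter", "SusC", False))
        for marker in b.electron_markers:
            roster.append((f"etm:{marker}", "electron_marker", marker, False))
        for i in range(b.n_filler):
            roster.append((f"fill:{i}", None, None, False))

        # secreted flags: the first k genes of each enzyme category
        def mark_secreted(prefix: str, k: int) -> None:
            n = 0
            for j, (role, kind, label, _) in enumerate(roster):
                if role.startswith(prefix) and n < k:
                    roster[j] = (role, kind, label, True)
                    n += 1

        mark_secreted("pep:", b.secreted_peptidases)
        mark_secreted("lip:", b.secreted_lipases)
        mark_secreted("caz:", b.secreted_cazymes)

        # --- contigs and gene placement
        lo, hi = b.contig_length_range
        drawn = rng.integers(lo, hi, b.n_contigs)
        cursors = np.zeros(b.n_contigs, dtype=int)
        gene_ids: list[str] = []
        for i, (role, kind, label, secreted) in enumerate(roster):
            gid = f"{b.bin_id}|{role}"
            c = i % b.n_contigs
            length = int(rng.integers(200, 800)) * 3  # bp, codon multiple
            start = int(cursors[c]) + 1
            end = start + length - 1
            cursors[c] = end + 50
            strand = "+" if rng.random() < 0.5 else "-"
            contig_id = f"{b.bin_id}|c{c}"
            gene_rows.append({
                "gene_id": gid, "bin_id": b.bin_id, "contig_id": contig_id,
                "start": start, "end": end, "strand": strand,
            })
            gene_ids.append(gid)
            gene_bp[gid] = length
            gene_bin[gid] = b.bin_id
            aa_len = length // 3
            qlen_rows.append({"gene_id": gid, "length": aa_len})
            signal_rows.append({"gene_id": gid,
                                "call": "SP" if secreted else "OTHER"})
            if kind is not None:
                add_hit(gid, aa_len, kind, label)
            else:
                # fillers: decoys below the identity filter, plus a few
                # above-identity but below-coverage hits
                if rng.random() < 0.5:
                    add_hit(gid, aa_len, "peptidase", "M01", planted=False)
                if rng.random() < 0.2:
                    add_hit(gid, aa_len, "peptidase", "S01A",
                            planted=True, low_coverage=True)
            baseline[gid] = float(
                rng.lognormal(mean=np.log(spec.baseline_level), sigma=0.8)
            )
        contig_lengths = np.maximum(drawn, cursors + 100)
        for c in range(b.n_contigs):
            contig_rows.append({"contig_id": f"{b.bin_id}|c{c}",
                                "bin_id": b.bin_id,
                                "length": int(contig_lengths[c])})

        # --- expression overrides for pathway genes in their own culture
        sym_to_gid = {sym: f"{b.bin_id}|pw:{sym}" for sym in symbols}
        bin_depth = (b.abundance * spec.community_depth if retained else 2.0)
        for aa, plan in sorted(b.pathways.items()):
            if aa not in substrate_samples:
                continue
            route = _route_for(catalog, aa, plan.route)
            sample = substrate_samples[aa]
            complete = plan.missing == 0
            level = spec.expr_level if (complete and plan.expressed) else 0.0
            for sym in route.genes[plan.missing:]:
                gid = sym_to_gid[sym]
                override[(sample, gid)] = level
                if retained:
                    truth["pathway_gene_expression"].append({
                        "bin_id": b.bin_id, "aa": aa, "sample_id": sample,
                        "gene_id": gid, "gene_symbol": sym,
                        "expressed": level > 0,
                        "expected_count": level * bin_depth
                        * gene_bp[gid] / 1000.0,
                    })
        # highly-expressed secreted peptidases: hot in every sample
        hot = [g for g in gene_ids
               if g.split("|", 1)[1].startswith("pep:")][:
               b.n_high_expressed_secreted]
        for gid in hot:
            baseline[gid] = spec.high_level

        # --- truth bookkeeping for retained bins
        if retained:
            symset = set(symbols) | set(b.extra_symbols)
            encoded = _truth_encoded(symset, catalog)
            expressed = {
                aa: bool(encoded[aa]) and any(
                    plan.missing == 0 and plan.expressed
                    and _route_for(catalog, aa2, plan.route).aa == aa
                    for aa2, plan in b.pathways.items() if aa2 == aa
                )
                for aa in encoded
            }
            # an amino acid whose route became complete only via symbols
            # shared with another planted route is encoded but silent
            truth["encoded_detail"][b.bin_id] = encoded
            truth["expressed_detail"][b.bin_id] = expressed
            truth["encoded_aa"][b.bin_id] = sum(encoded.values())
            truth["expressed_aa"][b.bin_id] = sum(expressed.values())
            truth["category_counts"][b.bin_id] = {
                "peptidase_total": sum(b.peptidases_by_type.values()),
                "peptidases_by_type": dict(sorted(
                    b.peptidases_by_type.items())),
                "secreted_peptidases": b.secreted_peptidases,
                "lipases": b.lipases,
                "secreted_lipases": b.secreted_lipases,
                "glycoside_hydrolases": b.cazymes_gh,
                "cazymes": b.cazymes_gh + b.cazymes_other,
                "secreted_cazymes": b.secreted_cazymes,
                "adhesion_genes": sum(b.adhesion.values()),
                "susC_genes": b.susc_polypeptide + b.susc_glucan,
                "electron_markers": sorted(b.electron_markers),
            }

    # --- depth tables (one row per sample x contig)
    depth_rows = []
    contig_df = pd.DataFrame(contig_rows,
                             columns=["contig_id", "bin_id", "length"])
    bin_depths = {b.bin_id: b.abundance * spec.community_depth
                  for b in spec.bins}
    bin_depths.update({b.bin_id: 2.0 for b in spec.qc_fail_bins})
    for aa in spec.substrates:
        sample = substrate_samples[aa]
        for row in contig_df.itertuples():
            lam = bin_depths[row.bin_id] * row.length / spec.read_length
            if spec.noise:
                n_reads = rng.poisson(lam)
                depth_val = n_reads * spec.read_length / row.length
            else:
                depth_val = bin_depths[row.bin_id]
            depth_rows.append({"sample_id": sample,
                               "contig_id": row.contig_id,
                               "length": int(row.length),
                               "mean_depth": float(depth_val)})

    # --- count tables (one row per sample x gene, zeros kept)
    count_rows = []
    gene_order = [r["gene_id"] for r in gene_rows]
    for aa in spec.substrates:
        sample = substrate_samples[aa]
        for gid in gene_order:
            level = override.get((sample, gid), baseline[gid])
            depth_b = bin_depths[gene_bin[gid]]
            mean = level * depth_b * gene_bp[gid] / 1000.0
            if spec.noise:
                count = int(rng.poisson(mean))
            else:
                count = int(round(mean)) if mean == 0 or mean >= 0.5 \
                    else 1  # noise-free: positive means stay positive
            count_rows.append({"sample_id": sample, "gene_id": gid,
                               "count": count})

    # --- identity tables for novelty calls
    ssu_rows, aai_rows, susc_rows = [], [], []
    susc_label_rows = [
        {"reference_id": "ref|susc|poly", "cluster_label": "polypeptide"},
        {"reference_id": "ref|susc|aglu", "cluster_label": "alpha_glucan"},
        {"reference_id": "ref|susc|bglu", "cluster_label": "beta_glucan"},
    ]
    ssu_refs = [f"ref|16S|fam{i}" for i in range(4)]
    aai_refs = [f"ref|genome|fam{i}" for i in range(3)]
    for b in spec.bins:
        if b.ssu_best_identity is not None:
            truth["ssu_best_identity"][b.bin_id] = b.ssu_best_identity
            others = [
                float(b.ssu_best_identity - rng.uniform(2.0, 12.0))
                for _ in ssu_refs[1:]
            ]
            vals = [b.ssu_best_identity] + [max(v, 0.0) for v in others]
            for ref, v in zip(ssu_refs, vals):
                ssu_rows.append({"query_id": b.bin_id, "reference_id": ref,
                                 "identity": round(v, 1)})
        if b.aai_best is not None:
            truth["aai_best"][b.bin_id] = b.aai_best
            vals = [b.aai_best] + [
                max(b.aai_best - rng.uniform(2.0, 10.0), 0.0)
                for _ in aai_refs[1:]
            ]
            for ref, v in zip(aai_refs, vals):
                aai_rows.append({"query_id": b.bin_id, "reference_id": ref,
                                 "aai": round(v, 1)})
        for i in range(b.susc_polypeptide + b.susc_glucan):
            gid = f"{b.bin_id}|susc:{i}"
            poly = i < b.susc_polypeptide
            near = rng.uniform(55.0, 70.0)
            far = rng.uniform(30.0, 45.0)
            susc_rows.append({"query_id": gid,
                              "reference_id": "ref|susc|poly",
                              "identity": round(near if poly else far, 1)})
            for ref in ("ref|susc|aglu", "ref|susc|bglu"):
                susc_rows.append({"query_id": gid, "reference_id": ref,
                                  "identity": round(
                                      (far if poly else near)
                                      - rng.uniform(0.0, 5.0), 1)})
            truth["susc_clusters"][gid] = (
                "polypeptide" if poly else "glucan")

    hits_df = pd.DataFrame(hit_rows, columns=list(range(12)))
    refmap_df = pd.DataFrame(
        [{"subject_id": s, "category_kind": k, "category_label": l}
         for s, (k, l) in sorted(refmap.items())],
        columns=["subject_id", "category_kind", "category_label"],
    )
    return SyntheticCommunity(
        spec=spec,
        qc=pd.DataFrame(qc_rows),
        contigs=contig_df,
        genes=pd.DataFrame(gene_rows),
        hits=hits_df,
        query_lengths=pd.DataFrame(qlen_rows),
        reference_map=refmap_df,
        signal=pd.DataFrame(signal_rows),
        depth=pd.DataFrame(depth_rows),
        counts=pd.DataFrame(count_rows),
        substrate_map=pd.DataFrame(
            [{"aa": aa, "sample_id": s}
             for aa, s in substrate_samples.items()]
        ),
        ssu_identity=pd.DataFrame(
            ssu_rows, columns=["query_id", "reference_id", "identity"]),
        aai_identity=pd.DataFrame(
            aai_rows, columns=["query_id", "reference_id", "aai"]),
        susc_identity=pd.DataFrame(
            susc_rows, columns=["query_id", "reference_id", "identity"]),
        susc_labels=pd.DataFrame(susc_label_rows),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# the emulated study design

def _plans(encoded_missing: Mapping[str, int],
           not_expressed: Sequence[str],
           routes: Mapping[str, str] | None = None,
           all_aas: Sequence[str] = AMINO_ACIDS) -> dict[str, PathwayPlan]:
    """Plant every amino acid: complete+expressed by default, complete but
    silent for ``not_expressed``, missing-k for keys of
    ``encoded_missing``."""
    routes = routes or {}
    plans = {}
    for aa in all_aas:
        if aa in encoded_missing:
            plans[aa] = PathwayPlan(route=routes.get(aa),
                                    missing=encoded_missing[aa])
        else:
            plans[aa] = PathwayPlan(route=routes.get(aa),
                                    expressed=aa not in not_expressed)
    return plans


def emulate_study_design(seed: int = 0, noise: bool = True,
                         mean_depth: float = 20.0) -> CommunitySpec:
    """Default community mirroring the enrichment-study contrast.

    Twenty single-amino-acid cultures; a dominant proteolytic guild of
    three bins (high abundance, large secreted-peptidase complements,
    16/17/17 amino acids encoded and 16/11/17 expressed) against a
    minority guild of two cultured-type amino-acid fermenters (low
    abundance, few secreted peptidases, 13/16 encoded but only 5/2
    expressed), plus five generalist background bins and one bin failing
    the QC filter.
    """
    prot_1 = BinSpec(
        bin_id="proteo_1", abundance=0.091,
        completeness=96.0, contamination=1.5,
        pathways=_plans(
            {"threonine": 1, "histidine": 1, "methionine": 1, "tyrosine": 1},
            not_expressed=(),
            routes={"threonine": "threonine_dehydrogenase"},
        ),
        extra_symbols=("alaT",),
        peptidases_by_type={"M": 70, "S": 62, "C": 36, "other": 4},
        secreted_peptidases=72,
        lipases=3, secreted_lipases=1,
        cazymes_gh=21, cazymes_other=5, secreted_cazymes=6,
        adhesion={"PF01103": 1, "PF00754": 1, "PF02494": 1},
        susc_polypeptide=2, susc_glucan=1,
        n_high_expressed_secreted=38,
        aai_best=56.2,  # no 16S gene recovered from this bin
        electron_markers=ELECTRON_DEFAULT,
    )
    prot_2 = BinSpec(
        bin_id="proteo_2", abundance=0.026,
        completeness=92.0, contamination=2.1,
        pathways=_plans(
            {"lysine": 8, "tryptophan": 1, "tyrosine": 1},
            not_expressed=("glycine", "proline", "glutamine", "histidine",
                           "methionine", "arginine"),
        ),
        peptidases_by_type={"M": 45, "S": 42, "C": 19, "other": 3},
        secreted_peptidases=55,
        lipases=12, secreted_lipases=4,
        cazymes_gh=57, cazymes_other=8, secreted_cazymes=15,
        adhesion={"PF01103": 2, "PF00754": 2, "PF02494": 2},
        susc_polypeptide=3, susc_glucan=2,
        n_high_expressed_secreted=16,
        ssu_best_identity=85.3, aai_best=52.4,
        electron_markers=ELECTRON_DEFAULT,
    )
    prot_3 = BinSpec(
        bin_id="proteo_3", abundance=0.202,
        completeness=97.5, contamination=0.8,
        pathways=_plans(
            {"lysine": 8, "tyrosine": 1, "cysteine": 1},
            not_expressed=(),
        ),
        peptidases_by_type={"M": 42, "S": 41, "C": 16, "other": 1},
        secreted_peptidases=68,
        lipases=12, secreted_lipases=5,
        cazymes_gh=41, cazymes_other=6, secreted_cazymes=10,
        adhesion={"PF01103": 2, "PF00754": 2, "PF02494": 3},
        susc_polypeptide=6, susc_glucan=2,
        n_high_expressed_secreted=30,
        ssu_best_identity=88.1, aai_best=57.6,
        electron_markers=ELECTRON_DEFAULT,
    )
    ferm_1 = BinSpec(
        bin_id="ferm_1", abundance=0.004,
        completeness=94.0, contamination=1.0,
        pathways=_plans(
            {"lysine": 1, "threonine": 1, "histidine": 1, "methionine": 1,
             "tryptophan": 1, "phenylalanine": 1, "tyrosine": 1},
            not_expressed=("alanine", "arginine", "glutamine", "glycine",
                           "isoleucine", "leucine", "proline", "valine"),
        ),
        peptidases_by_type={"M": 12, "S": 11, "C": 5, "other": 2},
        secreted_peptidases=12,
        lipases=2, cazymes_gh=4,
        adhesion={"PF02496": 1},
        electron_markers=("Hyd",),
        ssu_best_identity=97.2, aai_best=71.5,
    )
    ferm_2 = BinSpec(
        bin_id="ferm_2", abundance=0.002,
        completeness=91.0, contamination=2.8,
        pathways=_plans(
            {"threonine": 1, "tryptophan": 1, "phenylalanine": 1,
             "tyrosine": 1},
            not_expressed=("alanine", "arginine", "asparagine", "aspartate",
                           "cysteine", "glutamine", "glycine", "histidine",
                           "isoleucine", "leucine", "lysine", "methionine",
                           "proline", "valine"),
        ),
        peptidases_by_type={"M": 10, "S": 9, "C": 4, "other": 2},
        secreted_peptidases=8,
        lipases=1, cazymes_gh=3,
        electron_markers=("Hyd",),
        ssu_best_identity=96.8, aai_best=74.0,
    )
    background_aas = [
        ("alanine", "glutamate", "serine", "glycine", "aspartate"),
        ("glutamate", "aspartate", "asparagine", "serine"),
        ("alanine", "glutamate", "cysteine", "glycine"),
        ("serine", "glutamate", "aspartate", "arginine", "glycine"),
        ("alanine", "serine", "glutamate"),
    ]
    backgrounds = []
    for i, aas in enumerate(background_aas, start=1):
        backgrounds.append(BinSpec(
            bin_id=f"bg_{i}", abundance=0.135,
            completeness=88.0 + i, contamination=3.0 - 0.3 * i,
            pathways={aa: PathwayPlan(expressed=(j < 2))
                      for j, aa in enumerate(aas)},
            peptidases_by_type={"M": 4, "S": 4, "C": 1},
            secreted_peptidases=2,
            lipases=2, cazymes_gh=8, cazymes_other=2, secreted_cazymes=3,
            electron_markers=("Hyd", "Fdh"),
        ))
    qc_fail = BinSpec(
        bin_id="lowqual_1", abundance=0.0,
        completeness=85.0, contamination=7.5,
        pathways={"alanine": PathwayPlan(expressed=True)},
        peptidases_by_type={"M": 3, "S": 2},
        secreted_peptidases=1,
    )
    return CommunitySpec(
        bins=[prot_1, prot_2, prot_3, ferm_1, ferm_2] + backgrounds,
        qc_fail_bins=[qc_fail],
        mean_depth=mean_depth,
        noise=noise,
        seed=seed,
    )
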