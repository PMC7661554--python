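"""Genome abundance from contig coverage, RPKM expression, and
mapped-read-fraction prevalence.

Genome coverage is the length-weighted mean of per-contig read depths;
relative abundance in a sample is a genome's coverage divided by the total
coverage of all retained genomes in that sample. Expression uses RPKM
(reads per kilobase of transcript per million mapped reads), with the
per-sample mapped total taken over the gene catalog of all retained bins.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import ContigDepthRecord, GenomeBin, ValidationError

log = logging.getLogger(__name__)


def genome_coverage(depths: Iterable[ContigDepthRecord]) -> float:
    """Length-weighted mean depth over a bin's contigs:
    sum(depth_i * length_i) / sum(length_i)."""
    total_len = 0
    weighted = 0.0
    for rec in depths:
        total_len += rec.length
        weighted += rec.mean_depth * rec.length
    if total_len == 0:
        raise ValidationError("genome_coverage: zero total contig length")
    return weighted / total_len


def relative_abundance(coverages: Mapping[str, float]) -> dict[str, float]:
    """Normalize per-bin coverages to fractions summing to 1.

    All-zero samples yield NaN for every bin, with a warning.
    """
    for bin_id, cov in coverages.items():
        if cov < 0:
            raise ValidationError(f"bin {bin_id}: negative coverage {cov}")
    total = sum(coverages.values())
    if total == 0:
        log.warning("all coverages zero; relative abundance undefined")
        return {bin_id: float("nan") for bin_id in coverages}
    return {bin_id: cov / total for bin_id, cov in coverages.items()}


def compute_rpkm(count: int, gene_length: int, total_mapped: int) -> float:
    """RPKM = count / (gene_length/1000) / (total_mapped/1e6)."""
    if gene_length <= 0:
        raise ValidationError(f"non-positive gene length {gene_length}")
    if total_mapped <= 0:
        raise ValidationError("total mapped reads must be positive")
    return count / (gene_length / 1000.0) / (total_mapped / 1e6)


def mapped_fraction(mapped: int, total: int) -> float:
    """Percent of a dataset's reads mapped to a bin."""
    if total <= 0:
        raise ValidationError("total reads must be positive")
    if not 0 <= mapped <= total:
        raise ValidationError(f"mapped {mapped} outside [0, {total}]")
    return 100.0 * mapped / total


# ---------------------------------------------------------------------------
# table-level drivers

def abundance_table(bins: Sequence[GenomeBin],
                    depth: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, bin) coverage and relative abundance.

    ``depth`` holds sample_id, contig_id, length, mean_depth. Contigs of a
    bin missing from a sample's depth table are treated as depth 0 (warned);
    reads on contigs outside the retained bins are ignored.
    """
    contig_bin = {}
    contig_len = {}
    for b in bins:
        for contig_id, length in b.contigs:
            contig_bin[contig_id] = b.bin_id
            contig_len[contig_id] = length

    rows = []
    for sample_id, grp in depth.groupby("sample_id", sort=True):
        seen = dict(zip(grp.contig_id, grp.mean_depth))
        n_missing = 0
        coverages = {}
        for b in bins:
            records = []
            for contig_id, length in b.contigs:
                d = seen.get(contig_id)
                if d is None:
                    d = 0.0
                    n_missing += 1
                records.append(ContigDepthRecord(sample_id, contig_id,
                                                 length, float(d)))
            coverages[b.bin_id] = genome_coverage(records)
        if n_missing:
            log.warning("sample %s: %d bin contigs absent from depth table, "
                        "treated as depth 0", sample_id, n_missing)
        fracs = relative_abundance(coverages)
        for b in bins:
            rows.append({
                "sample_id": sample_id,
                "bin_id": b.bin_id,
                "coverage": coverages[b.bin_id],
                "relative_abundance": fracs[b.bin_id],
            })
    return pd.DataFrame(
        rows, columns=["sample_id", "bin_id", "coverage", "relative_abundance"]
    )


def rpkm_table(counts: pd.DataFrame,
               gene_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Per (sample, gene) RPKM from the long count table.

    Genes absent from ``gene_lengths`` (i.e. outside the retained bins'
    catalog) are dropped; the per-sample mapped total is summed over the
    retained genes only.
    """
    keep = counts[counts.gene_id.isin(gene_lengths.keys())].copy()
    n_drop = len(counts) - len(keep)
    if n_drop:
        log.info("rpkm_table: dropped %d count rows outside the gene catalog",
                 n_drop)
    rows = []
    for sample_id, grp in keep.groupby("sample_id", sort=True):
        total = int(grp["count"].sum())
        for row in grp.itertuples():
            if total == 0:
                rpkm = 0.0
            else:
                rpkm = compute_rpkm(int(row.count), gene_lengths[row.gene_id],
                                    total)
            rows.append({
                "sample_id": sample_id,
                "gene_id": row.gene_id,
                "count": int(row.count),
                "rpkm": rpkm,
                "total_mapped": total,
            })
    return pd.DataFrame(
        rows, columns=["sample_id", "gene_id", "count", "rpkm", "total_mapped"]
    )


def prevalence_table(mapping_stats: pd.DataFrame) -> pd.DataFrame:
    """Mapped-read prevalence per (dataset, bin).

    Input columns: dataset_id, bin_id, mapped_reads, total_reads.
    """
    rows = []
    for row in mapping_stats.itertuples():
        rows.append({
            "dataset_id": row.dataset_id,
            "bin_id": row.bin_id,
            "mapped_fraction": mapped_fraction(int(row.mapped_reads),
                                               int(row.total_reads)),
        })
    return pd.DataFrame(rows, columns=["dataset_id", "bin_id",
                                       "mapped_fraction"])
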