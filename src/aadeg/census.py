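"""Per-bin functional census: adhesion domains, secreted hydrolytic
enzymes, transporters, electron-transfer markers, and "highly expressed"
calls.

A gene is a secreted enzyme of category X when it carries a category-X
assignment AND a signal-peptide call. Peptidases are broken down by
catalytic type from the first letter of their MEROPS-style family code
(M metallo, S serine, C cysteine, ...). A gene counts as highly expressed
in a sample when its RPKM is strictly above the median RPKM of all genes
of its bin in that sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import CategoryAssignment
from .io_tables import GeneRecord, ValidationError

log = logging.getLogger(__name__)

#: default Pfam accessions screened for surface adhesion
ADHESION_ACCESSIONS = frozenset({"PF01103", "PF00754", "PF02494", "PF02496"})

#: electron-transfer / energy-conservation marker sets
ELECTRON_MARKERS = ("Hyd", "Fdh", "Rnf", "QFR", "NQR")

PEPTIDASE_TYPES = ("M", "S", "C", "other")


@dataclass
class HighlyExpressed:
    """Result of the bin-median expression screen in one sample."""

    genes: set[str]
    fold: dict[str, float]
    median: float


def peptidase_type(family_code: str) -> str:
    """Catalytic type from a MEROPS-style family code's first letter."""
    first = family_code[:1].upper()
    return first if first in ("M", "S", "C") else "other"


def adhesion_census(
    assignments: Iterable[CategoryAssignment],
    gene_bins: Mapping[str, str],
    adhesion_accessions: frozenset[str] = ADHESION_ACCESSIONS,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Count genes (not domains) carrying at least one listed adhesion
    accession, per bin; plus a per-accession gene breakdown."""
    per_bin_genes: dict[str, set[str]] = {}
    rows = []
    for a in assignments:
        if a.category_kind != "adhesion":
            continue
        if a.category_label not in adhesion_accessions:
            continue
        bin_id = gene_bins.get(a.gene_id)
        if bin_id is None:
            continue
        per_bin_genes.setdefault(bin_id, set()).add(a.gene_id)
        rows.append({"bin_id": bin_id, "accession": a.category_label,
                     "gene_id": a.gene_id})
    counts = {bin_id: len(genes) for bin_id, genes in per_bin_genes.items()}
    breakdown = pd.DataFrame(rows, columns=["bin_id", "accession", "gene_id"])
    return counts, breakdown.sort_values(
        ["bin_id", "accession", "gene_id"]).reset_index(drop=True)


def secreted_census(
    assignments: Iterable[CategoryAssignment],
    signal_calls: Mapping[str, bool],
    gene_bins: Mapping[str, str],
    kinds: Sequence[str] = ("peptidase", "lipase", "cazyme"),
) -> pd.DataFrame:
    """Per-bin counts of total and secreted genes per enzyme category.

    Genes absent from the signal table are treated as lacking a signal
    peptide (count logged once).
    """
    n_missing = 0
    tally: dict[tuple[str, str], dict[str, int]] = {}
    for a in assignments:
        if a.category_kind not in kinds:
            continue
        bin_id = gene_bins.get(a.gene_id)
        if bin_id is None:
            continue
        if a.gene_id not in signal_calls:
            n_missing += 1
        secreted = signal_calls.get(a.gene_id, False)
        cell = tally.setdefault((bin_id, a.category_kind),
                                {"total": 0, "secreted": 0})
        cell["total"] += 1
        cell["secreted"] += int(secreted)
    if n_missing:
        log.warning("secreted_census: %d enzyme genes absent from the "
                    "signal-peptide table, treated as not secreted", n_missing)
    rows = [
        {"bin_id": bin_id, "category": kind,
         "total": cell["total"], "secreted": cell["secreted"]}
        for (bin_id, kind), cell in sorted(tally.items())
    ]
    return pd.DataFrame(rows, columns=["bin_id", "category", "total",
                                       "secreted"])


def highly_expressed(rpkm: Mapping[str, float]) -> HighlyExpressed:
    """Genes of one bin/sample with RPKM strictly above the bin median.

    The median runs over ALL genes of the bin, zeros included. When the
    median is 0, genes with positive RPKM are flagged with infinite fold.
    """
    if not rpkm:
        raise ValidationError("highly_expressed: empty gene set")
    values = np.array(list(rpkm.values()), dtype=float)
    med = float(np.median(values))
    genes = {g for g, v in rpkm.items() if v > med}
    fold = {
        g: (rpkm[g] / med if med > 0 else math.inf)
        for g in genes
    }
    return HighlyExpressed(genes=genes, fold=fold, median=med)


# ---------------------------------------------------------------------------
# full census tables

def census_table(
    assignments: Sequence[CategoryAssignment],
    signal_calls: Mapping[str, bool],
    gene_bins: Mapping[str, str],
    bin_ids: Sequence[str],
    adhesion_accessions: frozenset[str] = ADHESION_ACCESSIONS,
) -> pd.DataFrame:
    """One row per bin with the full static census.

    Columns: adhesion_genes; peptidase_total and peptidase_M/S/C/other;
    secreted_peptidases/lipases/cazymes; lipases; cazymes;
    glycoside_hydrolases (cazyme labels starting GH); susC_genes
    (transporter labels starting SusC); one column per electron marker.
    """
    adhesion_counts, _ = adhesion_census(assignments, gene_bins,
                                         adhesion_accessions)
    secreted = secreted_census(assignments, signal_calls, gene_bins)
    sec_map = {
        (row.bin_id, row.category): (row.total, row.secreted)
        for row in secreted.itertuples()
    }

    pept_types: dict[str, dict[str, int]] = {}
    gh: dict[str, int] = {}
    susc: dict[str, int] = {}
    markers: dict[tuple[str, str], int] = {}
    for a in assignments:
        bin_id = gene_bins.get(a.gene_id)
        if bin_id is None:
            continue
        if a.category_kind == "peptidase":
            t = peptidase_type(a.category_label)
            pept_types.setdefault(bin_id, dict.fromkeys(PEPTIDASE_TYPES, 0))
            pept_types[bin_id][t] += 1
        elif a.category_kind == "cazyme" and a.category_label.startswith("GH"):
            gh[bin_id] = gh.get(bin_id, 0) + 1
        elif (a.category_kind == "transporter"
              and a.category_label.startswith("SusC")):
            susc[bin_id] = susc.get(bin_id, 0) + 1
        elif a.category_kind == "electron_marker":
            key = (bin_id, a.category_label)
            markers[key] = markers.get(key, 0) + 1

    rows = []
    for bin_id in bin_ids:
        types = pept_types.get(bin_id, dict.fromkeys(PEPTIDASE_TYPES, 0))
        row = {
            "bin_id": bin_id,
            "adhesion_genes": adhesion_counts.get(bin_id, 0),
            "peptidase_total": sum(types.values()),
        }
        for t in PEPTIDASE_TYPES:
            row[f"peptidase_{t}"] = types[t]
        for kind, col in (("peptidase", "secreted_peptidases"),
                          ("lipase", "secreted_lipases"),
                          ("cazyme", "secreted_cazymes")):
            row[col] = sec_map.get((bin_id, kind), (0, 0))[1]
        row["lipases"] = sec_map.get((bin_id, "lipase"), (0, 0))[0]
        row["cazymes"] = sec_map.get((bin_id, "cazyme"), (0, 0))[0]
        row["glycoside_hydrolases"] = gh.get(bin_id, 0)
        row["susC_genes"] = susc.get(bin_id, 0)
        for m in ELECTRON_MARKERS:
            row[f"marker_{m}"] = markers.get((bin_id, m), 0)
        rows.append(row)
    return pd.DataFrame(rows)


def highly_expressed_table(
    rpkm_df: pd.DataFrame,
    assignments: Sequence[CategoryAssignment],
    signal_calls: Mapping[str, bool],
    gene_bins: Mapping[str, str],
) -> pd.DataFrame:
    """Per (bin, sample, category): highly-expressed gene counts.

    The screen runs on the full RPKM vector of each bin in each sample;
    reported categories are total genes, secreted peptidases, and each
    enzyme kind, plus a per-sample mean row is derivable downstream.
    """
    kind_genes: dict[tuple[str, str], set[str]] = {}
    for a in assignments:
        bin_id = gene_bins.get(a.gene_id)
        if bin_id is None:
            continue
        kind_genes.setdefault((bin_id, a.category_kind), set()).add(a.gene_id)
        if a.category_kind == "peptidase" and signal_calls.get(a.gene_id, False):
            kind_genes.setdefault((bin_id, "secreted_peptidase"),
                                  set()).add(a.gene_id)

    rows = []
    for sample_id, grp in rpkm_df.groupby("sample_id", sort=True):
        by_bin: dict[str, dict[str, float]] = {}
        for row in grp.itertuples():
            bin_id = gene_bins.get(row.gene_id)
            if bin_id is None:
                continue
            by_bin.setdefault(bin_id, {})[row.gene_id] = row.rpkm
        for bin_id, vec in sorted(by_bin.items()):
            he = highly_expressed(vec)
            rows.append({"sample_id": sample_id, "bin_id": bin_id,
                         "category": "all_genes", "n_genes": len(vec),
                         "n_highly_expressed": len(he.genes),
                         "median_rpkm": he.median})
            for kind in ("peptidase", "secreted_peptidase", "lipase",
                         "cazyme"):
                members = kind_genes.get((bin_id, kind), set())
                rows.append({
                    "sample_id": sample_id, "bin_id": bin_id,
                    "category": kind, "n_genes": len(members),
                    "n_highly_expressed": len(members & he.genes),
                    "median_rpkm": he.median,
                })
    return pd.DataFrame(rows, columns=["sample_id", "bin_id", "category",
                                       "n_genes", "n_highly_expressed",
                                       "median_rpkm"])
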