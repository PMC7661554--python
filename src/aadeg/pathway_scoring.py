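"""Amino-acid catabolic pathway completeness and expression scoring.

A pathway is an explicit ordered gene list; it is *complete* in a bin only
when every gene symbol is present, and *expressed* in the culture fed its
amino acid only when, additionally, every gene has RPKM strictly above the
expression threshold (default 0) in that culture's metatranscriptome. An
amino acid counts as degradable (encoded/expressed) by a bin when at least
one of its alternative routes qualifies.

The shipped default catalog covers all 20 proteinogenic amino acids with
literature-standard anaerobic routes; it is data, not code, and can be
replaced by any catalog file with the same schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .io_tables import ValidationError

log = logging.getLogger(__name__)

AMINO_ACIDS = (
    "alanine", "arginine", "asparagine", "aspartate", "cysteine",
    "glutamate", "glutamine", "glycine", "histidine", "isoleucine",
    "leucine", "lysine", "methionine", "phenylalanine", "proline",
    "serine", "threonine", "tryptophan", "tyrosine", "valine",
)


@dataclass(frozen=True)
class PathwayDef:
    """One catabolic route for one amino acid."""

    aa: str
    pathway_id: str
    genes: tuple[str, ...]
    product: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(
                f"pathway {self.aa}/{self.pathway_id}: empty gene list"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(
                f"pathway {self.aa}/{self.pathway_id}: duplicate genes"
            )


def load_catalog(path: str | None = None) -> list[PathwayDef]:
    """Load a pathway catalog from YAML; default: the shipped catalog.

    Entries: aa, pathway_id, genes (non-empty list), product, ec (optional).
    Duplicate (aa, pathway_id) pairs are rejected. The shipped default is
    additionally checked to cover exactly the 20 amino acids.
    """
    if path is None:
        text = (resources.files("aadeg.data") / "aa_catalog.yaml").read_text()
        default = True
    else:
        with open(path) as fh:
            text = fh.read()
        default = False
    raw = yaml.safe_load(text)
    catalog: list[PathwayDef] = []
    seen: set[tuple[str, str]] = set()
    for entry in raw:
        key = (entry["aa"], entry["pathway_id"])
        if key in seen:
            raise ValidationError(f"duplicate pathway {key}")
        seen.add(key)
        catalog.append(
            PathwayDef(
                aa=entry["aa"],
                pathway_id=entry["pathway_id"],
                genes=tuple(entry["genes"]),
                product=entry.get("product", ""),
            )
        )
    if default:
        aas = {p.aa for p in catalog}
        if aas != set(AMINO_ACIDS):
            raise ValidationError(
                "shipped catalog does not cover exactly the 20 amino acids"
            )
    return catalog


def is_pathway_complete(
    bin_genes: set[str], pathway: PathwayDef
) -> tuple[bool, list[str]]:
    """True iff every pathway gene symbol is present; else the missing list."""
    missing = [g for g in pathway.genes if g not in bin_genes]
    return (not missing), missing


def encoded_aa_count(
    bin_genes: set[str], catalog: Sequence[PathwayDef]
) -> tuple[int, dict[str, list[tuple[str, bool, list[str]]]]]:
    """Number of amino acids with >=1 complete route, plus per-aa detail.

    Detail maps aa -> [(pathway_id, complete, missing_genes), ...].
    """
    detail: dict[str, list[tuple[str, bool, list[str]]]] = {}
    for p in catalog:
        complete, missing = is_pathway_complete(bin_genes, p)
        detail.setdefault(p.aa, []).append((p.pathway_id, complete, missing))
    count = sum(
        1 for routes in detail.values() if any(c for _, c, _ in routes)
    )
    return count, detail


def is_pathway_expressed(
    pathway: PathwayDef,
    gene_rpkm: Mapping[str, float],
    bin_genes: set[str],
    tau: float = 0.0,
) -> tuple[bool, str]:
    """True iff the pathway is complete in the bin AND every gene has RPKM
    strictly above ``tau`` in the culture fed this amino acid.

    Returns (verdict, reason); reasons: expressed, not_encoded,
    gene_not_expressed:<symbol>.
    """
    complete, _missing = is_pathway_complete(bin_genes, pathway)
    if not complete:
        return False, "not_encoded"
    for g in pathway.genes:
        if gene_rpkm.get(g, 0.0) <= tau:
            return False, f"gene_not_expressed:{g}"
    return True, "expressed"


def expressed_aa_count(
    bin_genes: set[str],
    catalog: Sequence[PathwayDef],
    rpkm_by_aa: Mapping[str, Mapping[str, float]],
    tau: float = 0.0,
) -> tuple[int, dict[str, bool]]:
    """Number of amino acids with >=1 expressed route in the culture fed
    that amino acid; OR-semantics over alternative routes."""
    expressed: dict[str, bool] = {}
    for p in catalog:
        if p.aa not in rpkm_by_aa:
            raise ValidationError(
                f"no substrate sample mapped for amino acid {p.aa}"
            )
        ok, _ = is_pathway_expressed(p, rpkm_by_aa[p.aa], bin_genes, tau)
        expressed[p.aa] = expressed.get(p.aa, False) or ok
    return sum(expressed.values()), expressed


def expression_matrix(
    bin_genes_by_bin: Mapping[str, set[str]],
    catalog: Sequence[PathwayDef],
    rpkm_df: pd.DataFrame,
    gene_symbol_map: Mapping[str, Mapping[str, str]],
    substrate_map: Mapping[str, str],
    tau: float = 0.0,
) -> pd.DataFrame:
    """Long table of per-gene pathway cells for a heat-table display.

    One row per (bin, aa, pathway, gene symbol) with presence, RPKM in the
    culture fed that aa, max-normalized RPKM within the (bin, aa, pathway)
    block, and the pathway verdicts. ``gene_symbol_map`` maps
    bin_id -> symbol -> gene_id so expression can be looked up per gene;
    symbols absent from the bin are flagged ``not_found`` (RPKM NaN).
    """
    missing_aas = [p.aa for p in catalog if p.aa not in substrate_map]
    if missing_aas:
        raise ValidationError(
            f"substrate map lacks samples for: {sorted(set(missing_aas))}"
        )
    rpkm_lookup = {
        (row.sample_id, row.gene_id): row.rpkm for row in rpkm_df.itertuples()
    }
    rows = []
    for bin_id in sorted(bin_genes_by_bin):
        bin_genes = bin_genes_by_bin[bin_id]
        symbol_map = gene_symbol_map.get(bin_id, {})
        for p in catalog:
            sample = substrate_map[p.aa]
            gene_rpkm = {}
            for sym in p.genes:
                gid = symbol_map.get(sym)
                if gid is not None:
                    gene_rpkm[sym] = rpkm_lookup.get((sample, gid), 0.0)
            encoded, _ = is_pathway_complete(bin_genes, p)
            expressed, reason = is_pathway_expressed(p, gene_rpkm,
                                                     bin_genes, tau)
            vals = [gene_rpkm.get(sym) for sym in p.genes]
            present_vals = [v for v in vals if v is not None]
            block_max = max(present_vals) if present_vals else 0.0
            for sym, v in zip(p.genes, vals):
                rows.append({
                    "bin_id": bin_id, "aa": p.aa, "pathway_id": p.pathway_id,
                    "gene_symbol": sym, "sample_id": sample,
                    "present": v is not None,
                    "rpkm": float("nan") if v is None else v,
                    "norm_rpkm": (0.0 if v is None or block_max == 0
                                  else v / block_max),
                    "encoded": encoded, "expressed": expressed,
                    "reason": reason,
                })
    return pd.DataFrame(
        rows, columns=["bin_id", "aa", "pathway_id", "gene_symbol",
                       "sample_id", "present", "rpkm", "norm_rpkm",
                       "encoded", "expressed", "reason"]
    )
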