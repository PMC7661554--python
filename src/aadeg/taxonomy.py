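"""Rank-level taxonomic novelty from 16S identity and AAI, and
nearest-labeled-reference SusC cluster assignment.

16S rRNA gene identity against the closest classified reference is compared
to rank thresholds (defaults: 86.5% for family, 94.5% for genus): below the
family threshold the query represents a novel family or higher rank; between
the two, a novel genus; at or above the genus threshold it falls within a
known genus. Genome-level AAI below ~60% likewise indicates a lineage
outside described families. Identities exactly at a threshold fall in the
less-novel class (configurable semantics documented in the methods note).

SusC transporter substrate class (polypeptide vs glucan cluster) is
assigned from the highest-identity labeled reference, an explicit
simplification of phylogenetic cluster placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io_tables import ValidationError

RANK_WITHIN_GENUS = "within_genus"
RANK_NOVEL_GENUS = "novel_genus"
RANK_NOVEL_FAMILY = "novel_family_or_higher"


@dataclass(frozen=True)
class NoveltyCall:
    query_id: str
    best_reference_id: str
    best_identity: float
    rank_call: str
    method: str


def classify_16s(best_identity: float, family_t: float = 86.5,
                 genus_t: float = 94.5) -> str:
    """Rank call from the best 16S identity against classified references."""
    if not family_t < genus_t:
        raise ValidationError(
            f"family threshold {family_t} must be below genus threshold "
            f"{genus_t}"
        )
    if not 0.0 <= best_identity <= 100.0:
        raise ValidationError(f"identity {best_identity} outside [0, 100]")
    if best_identity < family_t:
        return RANK_NOVEL_FAMILY
    if best_identity < genus_t:
        return RANK_NOVEL_GENUS
    return RANK_WITHIN_GENUS


def classify_aai(best_aai: float, family_cutoff: float = 60.0) -> str:
    """within_family / novel_family from the best AAI against cultured
    family representatives."""
    if not 0.0 <= best_aai <= 100.0:
        raise ValidationError(f"AAI {best_aai} outside [0, 100]")
    return "novel_family" if best_aai < family_cutoff else "within_family"


def assign_susc_cluster(
    identities: Mapping[str, float],
    reference_labels: Mapping[str, str],
) -> tuple[str, str, float]:
    """Label of the highest-identity labeled reference.

    Ties break lexicographically by reference_id (deterministic).
    Returns (cluster_label, reference_id, identity).
    """
    labeled = {r: v for r, v in identities.items() if r in reference_labels}
    if not labeled:
        raise ValidationError("no labeled reference with an identity value")
    best_ref = min(labeled, key=lambda r: (-labeled[r], r))
    return reference_labels[best_ref], best_ref, labeled[best_ref]


# ---------------------------------------------------------------------------
# table-level drivers

def novelty_table(identity_df: pd.DataFrame, method: str,
                  value_col: str = "identity",
                  family_t: float = 86.5, genus_t: float = 94.5,
                  aai_family_cutoff: float = 60.0) -> pd.DataFrame:
    """Per-query novelty calls from a long (query, reference, value) table.

    ``method`` is "16S" or "AAI"; the best (highest) value per query drives
    the call, with the per-reference rows retained for inspection upstream.
    """
    if method not in ("16S", "AAI"):
        raise ValidationError(f"unknown method {method!r}")
    rows = []
    for query_id, grp in identity_df.groupby("query_id", sort=True):
        best = grp.loc[grp[value_col].idxmax()]
        # deterministic tie-break on reference id
        ties = grp[grp[value_col] == best[value_col]]
        best = ties.sort_values("reference_id").iloc[0]
        value = float(best[value_col])
        if method == "16S":
            call = classify_16s(value, family_t, genus_t)
        else:
            call = classify_aai(value, aai_family_cutoff)
        rows.append({
            "query_id": query_id,
            "best_reference_id": best.reference_id,
            "best_identity": value,
            "rank_call": call,
            "method": method,
        })
    return pd.DataFrame(rows, columns=["query_id", "best_reference_id",
                                       "best_identity", "rank_call",
                                       "method"])


def susc_cluster_table(identity_df: pd.DataFrame,
                       reference_labels: Mapping[str, str]) -> pd.DataFrame:
    """Nearest-labeled-reference cluster per SusC query gene."""
    rows = []
    for query_id, grp in identity_df.groupby("query_id", sort=True):
        ids = dict(zip(grp.reference_id, grp.identity))
        label, ref, ident = assign_susc_cluster(ids, reference_labels)
        rows.append({"query_id": query_id, "cluster_label": label,
                     "reference_id": ref, "identity": ident})
    return pd.DataFrame(rows, columns=["query_id", "cluster_label",
                                       "reference_id", "identity"])
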