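"""Homology-hit filtering, best-hit resolution, functional category
assignment and average amino-acid identity (AAI).

The census of secreted enzymes and transporters rests on protein searches
against curated catalogs (MEROPS-style peptidase families, lipase and
transporter classifications, Pfam adhesion domains). Hits are accepted only
above strict identity and query-coverage cutoffs (default: both 50%,
exclusive), then reduced to one hit per gene and category kind. AAI between
two genomes is the mean identity over their reciprocal best hits and serves
as a genome-level taxonomic distance.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: category kinds a gene may carry simultaneously (one label per kind)
CATEGORY_KINDS = (
    "peptidase",
    "lipase",
    "transporter",
    "cazyme",
    "adhesion",
    "pathway_gene",
    "electron_marker",
)


@dataclass(frozen=True)
class HomologyHit:
    """One row of a 12-column tabular protein search.

    ``coverage`` is query coverage in percent (alignment length over query
    length); ``None`` when no query-length table was available, in which
    case coverage filtering is skipped for this hit with a warning.
    """

    query_id: str
    subject_id: str
    identity: float
    coverage: float | None
    bitscore: float
    evalue: float = 0.0
    aln_length: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(
                f"identity {self.identity} outside [0, 100] "
                f"for query {self.query_id!r}"
            )
        if self.coverage is not None and not 0.0 <= self.coverage <= 100.0:
            raise ValueError(
                f"coverage {self.coverage} outside [0, 100] "
                f"for query {self.query_id!r}"
            )
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore for query {self.query_id!r}")


@dataclass(frozen=True)
class CategoryAssignment:
    """A gene's membership in one functional category.

    After best-hit resolution there is at most one assignment per
    (gene, category_kind); a multi-domain gene may hold assignments in
    several kinds (e.g. a peptidase that also carries an adhesion domain).
    """

    gene_id: str
    category_kind: str
    category_label: str
    source_subject: str

    def __post_init__(self) -> None:
        if self.category_kind not in CATEGORY_KINDS:
            raise ValueError(f"unknown category_kind {self.category_kind!r}")


def _hit_rank(hit: HomologyHit) -> tuple:
    # best first: highest bitscore, then highest identity, then smallest subject
    return (-hit.bitscore, -hit.identity, hit.subject_id)


def filter_hits(
    hits: Iterable[HomologyHit],
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
) -> list[HomologyHit]:
    """Keep hits with identity strictly above ``min_identity`` and query
    coverage strictly above ``min_coverage``.

    Hits lacking coverage (no query-length table) pass the coverage clause;
    a single warning records how many were waved through.
    """
    kept: list[HomologyHit] = []
    n_no_cov = 0
    for hit in hits:
        if hit.identity <= min_identity:
            continue
        if hit.coverage is None:
            n_no_cov += 1
        elif hit.coverage <= min_coverage:
            continue
        kept.append(hit)
    if n_no_cov:
        log.warning(
            "coverage unavailable for %d hits; coverage filter skipped for them",
            n_no_cov,
        )
    return kept


def resolve_best_hit(hits: Iterable[HomologyHit]) -> dict[str, HomologyHit]:
    """One hit per query: highest bitscore, ties by higher identity, then
    lexicographically smallest subject_id."""
    best: dict[str, HomologyHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.query_id] = hit
    return best


def assign_categories(
    hits: Iterable[HomologyHit],
    reference_map: Mapping[str, tuple[str, str]],
) -> list[CategoryAssignment]:
    """Map filtered hits to functional categories.

    ``reference_map`` takes subject_id to ``(category_kind, category_label)``.
    The best hit is resolved independently within each (query, kind) group,
    so a gene may be assigned in several kinds but carries one label per
    kind. Hits to unmapped subjects are dropped (count logged).
    """
    _check_reference_map(reference_map)
    best: dict[tuple[str, str], HomologyHit] = {}
    n_unmapped = 0
    for hit in hits:
        entry = reference_map.get(hit.subject_id)
        if entry is None:
            n_unmapped += 1
            continue
        kind, _label = entry
        key = (hit.query_id, kind)
        cur = best.get(key)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[key] = hit
    if n_unmapped:
        log.info("dropped %d hits to subjects absent from the reference map",
                 n_unmapped)
    out = []
    for (gene_id, kind), hit in sorted(best.items()):
        out.append(
            CategoryAssignment(
                gene_id=gene_id,
                category_kind=kind,
                category_label=reference_map[hit.subject_id][1],
                source_subject=hit.subject_id,
            )
        )
    return out


def _check_reference_map(reference_map: Mapping[str, tuple[str, str]]) -> None:
    for subject, entry in reference_map.items():
        kind, _ = entry
        if kind not in CATEGORY_KINDS:
            raise ValueError(
                f"reference map subject {subject!r} has unknown kind {kind!r}"
            )


def compute_aai(
    hits_ab: Iterable[HomologyHit],
    hits_ba: Iterable[HomologyHit],
    rbh_min_identity: float = 30.0,
    rbh_min_coverage: float = 70.0,
) -> tuple[float | None, int]:
    """Average amino-acid identity between two genomes from their two
    directional hit tables.

    Reciprocal best hits: gene *a*'s best partner *b* (passing the RBH
    thresholds, inclusive) must itself point back to *a*. The AAI is the
    arithmetic mean over RBH pairs of the two directional identities,
    which makes the statistic exactly symmetric in the two genomes.
    Returns ``(None, 0)`` when no RBH exists.
    """

    def _best_partners(hits: Iterable[HomologyHit]) -> dict[str, HomologyHit]:
        ok = [
            h
            for h in hits
            if h.identity >= rbh_min_identity
            and (h.coverage is None or h.coverage >= rbh_min_coverage)
        ]
        return resolve_best_hit(ok)

    best_ab = _best_partners(hits_ab)
    best_ba = _best_partners(hits_ba)

    identities: list[float] = []
    for a, hit_ab in sorted(best_ab.items()):
        b = hit_ab.subject_id
        back = best_ba.get(b)
        if back is not None and back.subject_id == a:
            identities.append(0.5 * (hit_ab.identity + back.identity))
    if not identities:
        return None, 0
    return sum(identities) / len(identities), len(identities)
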