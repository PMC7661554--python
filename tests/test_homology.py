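"""Identity/coverage filtering, best-hit resolution, category assignment
and AAI, each checked against an independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aadeg.homology import (CategoryAssignment, HomologyHit,
                            assign_categories, compute_aai, filter_hits,
                            resolve_best_hit)


def make_hit(query="q", subject="s", identity=60.0, coverage=80.0,
             bitscore=100.0):
    return HomologyHit(query_id=query, subject_id=subject,
                       identity=identity, coverage=coverage,
                       bitscore=bitscore)


def random_hits(rng, n, n_queries=None, n_subjects=20):
    n_queries = n_queries or max(1, n // 3)
    return [
        make_hit(
            query=f"q{rng.integers(n_queries)}",
            subject=f"s{rng.integers(n_subjects)}",
            identity=float(np.round(rng.uniform(0, 100), 1)),
            coverage=float(np.round(rng.uniform(0, 100), 1)),
            bitscore=float(np.round(rng.uniform(0, 500), 1)),
        )
        for _ in range(n)
    ]


class TestFilterHits:
    @pytest.mark.parametrize(
        "identity,coverage,kept",
        [
            (49.9, 90.0, False),  # identity at/below cutoff removed
            (50.0, 90.0, False),  # exactly 50: strict inequality
            (50.1, 50.1, True),
            (90.0, 50.0, False),
            (90.0, 49.9, False),
        ],
    )
    def test_strict_boundaries(self, identity, coverage, kept):
        out = filter_hits([make_hit(identity=identity, coverage=coverage)])
        assert bool(out) is kept

    def test_matches_brute_force_scan(self, rng):
        hits = random_hits(rng, 200)
        got = filter_hits(hits, 50, 50)
        expected = [h for h in hits if h.identity > 50 and h.coverage > 50]
        assert got == expected

    def test_missing_coverage_passes_coverage_clause(self):
        hit = make_hit(identity=70.0, coverage=None)
        assert filter_hits([hit]) == [hit]
        assert filter_hits([make_hit(identity=30.0, coverage=None)]) == []

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_thresholds(self, data):
        hits = [
            make_hit(query=f"q{i}",
                     identity=data.draw(st.floats(0, 100)),
                     coverage=data.draw(st.floats(0, 100)))
            for i in range(10)
        ]
        hi_i = data.draw(st.floats(0, 100))
        hi_c = data.draw(st.floats(0, 100))
        lo_i = data.draw(st.floats(0, 100).filter(lambda x: x <= hi_i))
        lo_c = data.draw(st.floats(0, 100).filter(lambda x: x <= hi_c))
        strict = set(id(h) for h in filter_hits(hits, hi_i, hi_c))
        loose = set(id(h) for h in filter_hits(hits, lo_i, lo_c))
        assert strict <= loose


class TestResolveBestHit:
    def test_single_hit(self):
        h = make_hit()
        assert resolve_best_hit([h]) == {"q": h}

    def test_bitscore_dominates(self):
        lo = make_hit(subject="s1", bitscore=90)
        hi = make_hit(subject="s2", bitscore=100)
        assert resolve_best_hit([lo, hi])["q"] is hi

    def test_tie_break_identity_then_subject(self):
        a = make_hit(subject="sB", bitscore=100, identity=90)
        b = make_hit(subject="sA", bitscore=100, identity=90)
        c = make_hit(subject="sC", bitscore=100, identity=95)
        assert resolve_best_hit([a, b])["q"] is b      # subject lexicographic
        assert resolve_best_hit([a, b, c])["q"] is c   # identity first

    def test_matches_brute_force(self, rng):
        hits = random_hits(rng, 200, n_queries=50, n_subjects=5)
        got = resolve_best_hit(hits)
        by_query = {}
        for h in hits:
            by_query.setdefault(h.query_id, []).append(h)
        for q, group in by_query.items():
            best = sorted(group, key=lambda h: (-h.bitscore, -h.identity,
                                                h.subject_id))[0]
            assert got[q] == best


class TestAssignCategories:
    REF = {
        "merops|C01A": ("peptidase", "C01A"),
        "merops|S08A": ("peptidase", "S08A"),
        "pfam|PF01103": ("adhesion", "PF01103"),
    }

    def test_mapped_subject_yields_assignment(self):
        (a,) = assign_categories([make_hit(subject="merops|C01A")], self.REF)
        assert a == CategoryAssignment("q", "peptidase", "C01A",
                                       "merops|C01A")

    def test_unmapped_subject_dropped(self):
        assert assign_categories([make_hit(subject="nowhere")], self.REF) == []

    def test_multi_domain_gene_one_label_per_kind(self):
        hits = [
            make_hit(subject="merops|C01A", bitscore=100),
            make_hit(subject="merops|S08A", bitscore=120),
            make_hit(subject="pfam|PF01103", bitscore=50),
        ]
        out = assign_categories(hits, self.REF)
        kinds = {a.category_kind: a.category_label for a in out}
        assert kinds == {"peptidase": "S08A", "adhesion": "PF01103"}

    def test_counts_match_brute_force_tally(self, rng):
        ref = {f"s{i}": (("peptidase", "lipase", "adhesion")[i % 3],
                         f"L{i}") for i in range(9)}
        hits = random_hits(rng, 30, n_queries=10, n_subjects=12)
        out = assign_categories(hits, ref)
        # oracle: per (query, kind) keep best-ranked mapped hit
        expected = {}
        for h in hits:
            if h.subject_id not in ref:
                continue
            key = (h.query_id, ref[h.subject_id][0])
            cur = expected.get(key)
            rank = (-h.bitscore, -h.identity, h.subject_id)
            if cur is None or rank < cur[0]:
                expected[key] = (rank, ref[h.subject_id][1])
        assert {(a.gene_id, a.category_kind): a.category_label
                for a in out} == {k: v for k, (_, v) in expected.items()}


def directional_hits(rng, genes_a, genes_b, density=0.6):
    hits = []
    for a in genes_a:
        for b in genes_b:
            if rng.random() < density:
                hits.append(make_hit(query=a, subject=b,
                                     identity=float(rng.uniform(20, 100)),
                                     coverage=float(rng.uniform(40, 100)),
                                     bitscore=float(rng.uniform(10, 500))))
    return hits


def brute_force_aai(hits_ab, hits_ba, min_id=30.0, min_cov=70.0):
    """Independent RBH enumeration: full scans, no shared helpers."""
    def best(hits, query):
        cands = [h for h in hits
                 if h.query_id == query and h.identity >= min_id
                 and h.coverage >= min_cov]
        if not cands:
            return None
        return sorted(cands, key=lambda h: (-h.bitscore, -h.identity,
                                            h.subject_id))[0]

    identities = []
    for a in sorted({h.query_id for h in hits_ab}):
        fwd = best(hits_ab, a)
        if fwd is None:
            continue
        back = best(hits_ba, fwd.subject_id)
        if back is not None and back.subject_id == a:
            identities.append((fwd.identity + back.identity) / 2)
    if not identities:
        return None, 0
    return sum(identities) / len(identities), len(identities)


class TestAai:
    def test_self_comparison_is_100(self):
        genes = [f"g{i}" for i in range(7)]
        self_hits = [make_hit(query=g, subject=g, identity=100.0,
                              coverage=100.0, bitscore=500.0) for g in genes]
        aai, n = compute_aai(self_hits, self_hits)
        assert aai == 100.0
        assert n == len(genes)

    def test_two_rbh_hand_arithmetic(self):
        ab = [make_hit("a1", "b1", identity=60), make_hit("a2", "b2",
                                                          identity=70)]
        ba = [make_hit("b1", "a1", identity=60), make_hit("b2", "a2",
                                                          identity=70)]
        aai, n = compute_aai(ab, ba)
        assert aai == pytest.approx(65.0)
        assert n == 2

    def test_no_rbh_reported_missing(self):
        ab = [make_hit("a1", "b1", identity=90)]
        ba = [make_hit("b1", "a2", identity=90)]  # points elsewhere
        assert compute_aai(ab, ba) == (None, 0)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(25):
            genes_a = [f"a{i}" for i in range(20)]
            genes_b = [f"b{i}" for i in range(20)]
            ab = directional_hits(rng, genes_a, genes_b)
            ba = directional_hits(rng, genes_b, genes_a)
            got = compute_aai(ab, ba)
            expected = brute_force_aai(ab, ba)
            if expected[0] is None:
                assert got == expected
            else:
                assert got[1] == expected[1]
                assert got[0] == pytest.approx(expected[0])

    def test_symmetric_in_genomes(self, rng):
        genes_a = [f"a{i}" for i in range(15)]
        genes_b = [f"b{i}" for i in range(15)]
        ab = directional_hits(rng, genes_a, genes_b)
        ba = directional_hits(rng, genes_b, genes_a)
        fwd = compute_aai(ab, ba)
        rev = compute_aai(ba, ab)
        assert fwd[1] == rev[1]
        if fwd[0] is not None:
            assert fwd[0] == pytest.approx(rev[0])
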