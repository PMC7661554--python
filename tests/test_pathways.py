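"""Pathway catalog integrity, completeness, and expression scoring."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aadeg.io_tables import ValidationError
from aadeg.pathway_scoring import (AMINO_ACIDS, PathwayDef, encoded_aa_count,
                                   expressed_aa_count, expression_matrix,
                                   is_pathway_complete, is_pathway_expressed,
                                   load_catalog)

CATALOG = load_catalog()
ALL_SYMBOLS = sorted({g for p in CATALOG for g in p.genes})


def routes_of(aa):
    return [p for p in CATALOG if p.aa == aa]


class TestCatalog:
    def test_covers_exactly_20_amino_acids(self):
        assert {p.aa for p in CATALOG} == set(AMINO_ACIDS)
        assert len(AMINO_ACIDS) == 20

    def test_glycine_decarboxylating_route_has_six_genes(self):
        (route,) = [p for p in CATALOG
                    if p.pathway_id == "glycine_decarboxylating"]
        assert len(route.genes) == 6

    def test_alanine_has_single_gene_dehydrogenase_route(self):
        (route,) = [p for p in CATALOG
                    if p.pathway_id == "alanine_dehydrogenase"]
        assert route.genes == ("ald",)

    def test_threonine_has_three_alternative_routes(self):
        assert len(routes_of("threonine")) == 3

    def test_lysine_route_has_at_least_eight_genes(self):
        assert max(len(p.genes) for p in routes_of("lysine")) >= 8

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValidationError):
            PathwayDef(aa="alanine", pathway_id="x", genes=())

    def test_duplicate_pathway_rejected(self, tmp_path):
        p = tmp_path / "cat.yaml"
        p.write_text(
            "- {aa: alanine, pathway_id: x, genes: [a]}\n"
            "- {aa: alanine, pathway_id: x, genes: [b]}\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            load_catalog(str(p))


class TestCompleteness:
    GLY = [p for p in CATALOG if p.pathway_id == "glycine_decarboxylating"][0]

    def test_all_genes_present_is_complete(self):
        complete, missing = is_pathway_complete(set(self.GLY.genes), self.GLY)
        assert complete and missing == []

    def test_one_absent_gene_is_incomplete(self):
        symbols = set(self.GLY.genes) - {"gcvT"}
        complete, missing = is_pathway_complete(symbols, self.GLY)
        assert not complete
        assert missing == ["gcvT"]

    def test_empty_bin_is_incomplete(self):
        complete, missing = is_pathway_complete(set(), self.GLY)
        assert not complete
        assert len(missing) == len(self.GLY.genes)


class TestEncodedCount:
    def test_every_catalog_gene_gives_20(self):
        count, _ = encoded_aa_count(set(ALL_SYMBOLS), CATALOG)
        assert count == 20

    def test_only_alanine_dehydrogenase_gives_1(self):
        count, detail = encoded_aa_count({"ald"}, CATALOG)
        assert count == 1
        assert any(c for _, c, _ in detail["alanine"])

    def test_or_semantics_over_alternative_routes(self):
        # either threonine route alone suffices
        count_a, _ = encoded_aa_count({"ltaE"}, CATALOG)
        count_b, _ = encoded_aa_count({"tdh", "kbl"}, CATALOG)
        assert count_a == count_b == 1

    def test_matches_brute_force_catalog_scan(self, rng):
        for _ in range(100):
            k = int(rng.integers(0, len(ALL_SYMBOLS)))
            symbols = set(rng.choice(ALL_SYMBOLS, size=k, replace=False))
            count, _ = encoded_aa_count(symbols, CATALOG)
            expected_aas = set()
            for p in CATALOG:
                ok = True
                for g in p.genes:
                    if g not in symbols:
                        ok = False
                if ok:
                    expected_aas.add(p.aa)
            assert count == len(expected_aas)

    @given(st.sets(st.sampled_from(ALL_SYMBOLS)),
           st.sampled_from(ALL_SYMBOLS))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_adding_a_gene_never_decreases_count(self, symbols, extra):
        before, _ = encoded_aa_count(symbols, CATALOG)
        after, _ = encoded_aa_count(symbols | {extra}, CATALOG)
        assert after >= before


class TestExpression:
    GLY = TestCompleteness.GLY

    def test_all_genes_expressed(self):
        rpkm = {g: 1.0 for g in self.GLY.genes}
        ok, reason = is_pathway_expressed(self.GLY, rpkm,
                                          set(self.GLY.genes))
        assert ok and reason == "expressed"

    def test_one_silent_gene_blocks_expression(self):
        rpkm = {g: 1.0 for g in self.GLY.genes}
        rpkm["gcvH"] = 0.0
        ok, reason = is_pathway_expressed(self.GLY, rpkm,
                                          set(self.GLY.genes))
        assert not ok
        assert reason == "gene_not_expressed:gcvH"

    def test_not_encoded_is_never_expressed(self):
        rpkm = {g: 99.0 for g in self.GLY.genes}
        ok, reason = is_pathway_expressed(self.GLY, rpkm,
                                          set(self.GLY.genes) - {"lpd"})
        assert not ok and reason == "not_encoded"

    def test_expressed_count_bounded_by_encoded(self, rng):
        for _ in range(30):
            k = int(rng.integers(0, len(ALL_SYMBOLS)))
            symbols = set(rng.choice(ALL_SYMBOLS, size=k, replace=False))
            rpkm_by_aa = {
                aa: {g: float(rng.integers(0, 2)) for g in ALL_SYMBOLS}
                for aa in AMINO_ACIDS
            }
            n_expr, _ = expressed_aa_count(symbols, CATALOG, rpkm_by_aa)
            n_enc, _ = encoded_aa_count(symbols, CATALOG)
            assert n_expr <= n_enc

    def test_missing_substrate_sample_is_error(self):
        with pytest.raises(ValidationError, match="glycine"):
            expressed_aa_count(set(ALL_SYMBOLS), CATALOG,
                               {aa: {} for aa in AMINO_ACIDS
                                if aa != "glycine"})


class TestExpressionMatrix:
    def _tiny(self):
        catalog = [
            PathwayDef(aa="alanine", pathway_id="p1", genes=("ald",)),
            PathwayDef(aa="glycine", pathway_id="p2", genes=("gA", "gB")),
        ]
        substrate = {"alanine": "sA", "glycine": "sG"}
        bins = {"b1": {"ald", "gA", "gB"}, "b2": {"ald"}}
        symbol_map = {
            "b1": {"ald": "b1.1", "gA": "b1.2", "gB": "b1.3"},
            "b2": {"ald": "b2.1"},
        }
        rpkm = pd.DataFrame([
            {"sample_id": "sA", "gene_id": "b1.1", "rpkm": 5.0},
            {"sample_id": "sG", "gene_id": "b1.2", "rpkm": 2.0},
            {"sample_id": "sG", "gene_id": "b1.3", "rpkm": 0.0},
            {"sample_id": "sA", "gene_id": "b2.1", "rpkm": 0.0},
        ])
        return catalog, substrate, bins, symbol_map, rpkm

    def test_row_count_is_bins_times_route_genes(self):
        catalog, substrate, bins, symbol_map, rpkm = self._tiny()
        m = expression_matrix(bins, catalog, rpkm, symbol_map, substrate)
        assert len(m) == 2 * (1 + 2)

    def test_absent_gene_flagged_not_found(self):
        catalog, substrate, bins, symbol_map, rpkm = self._tiny()
        m = expression_matrix(bins, catalog, rpkm, symbol_map, substrate)
        cell = m[(m.bin_id == "b2") & (m.gene_symbol == "gA")].iloc[0]
        assert not cell.present
        assert pd.isna(cell.rpkm)

    def test_silent_gene_blocks_pathway_and_zero_rpkm_blocks_all(self):
        catalog, substrate, bins, symbol_map, rpkm = self._tiny()
        m = expression_matrix(bins, catalog, rpkm, symbol_map, substrate)
        gly_b1 = m[(m.bin_id == "b1") & (m.aa == "glycine")]
        assert not gly_b1.expressed.any()
        zero = rpkm.assign(rpkm=0.0)
        m0 = expression_matrix(bins, catalog, zero, symbol_map, substrate)
        assert not m0.expressed.any()

    def test_expressed_implies_encoded(self):
        catalog, substrate, bins, symbol_map, rpkm = self._tiny()
        m = expression_matrix(bins, catalog, rpkm, symbol_map, substrate)
        assert (m.encoded | ~m.expressed).all()
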