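"""Functional census tallies and the bin-median highly-expressed screen."""

import math

import numpy as np
import pytest

from aadeg.census import (adhesion_census, census_table, highly_expressed,
                          peptidase_type, secreted_census)
from aadeg.homology import CategoryAssignment
from aadeg.io_tables import ValidationError


def assign(gene, kind, label):
    return CategoryAssignment(gene_id=gene, category_kind=kind,
                              category_label=label, source_subject=label)


class TestAdhesionCensus:
    def test_hand_tally(self):
        assigns = [assign("g1", "adhesion", "PF01103"),
                   assign("g2", "adhesion", "PF01103"),
                   assign("g3", "adhesion", "PF02494")]
        bins = {"g1": "b1", "g2": "b1", "g3": "b1"}
        counts, breakdown = adhesion_census(assigns, bins)
        assert counts == {"b1": 3}
        assert len(breakdown) == 3

    def test_no_adhesion_is_zero(self):
        counts, _ = adhesion_census([assign("g1", "peptidase", "C01A")],
                                    {"g1": "b1"})
        assert counts == {}

    def test_unlisted_accession_ignored(self):
        counts, _ = adhesion_census([assign("g1", "adhesion", "PF99999")],
                                    {"g1": "b1"})
        assert counts == {}


class TestSecretedCensus:
    def test_hand_tally(self):
        assigns = [assign(f"g{i}", "peptidase", "M01") for i in range(5)]
        signal = {"g0": True, "g1": True, "g2": True, "g3": False}
        bins = {f"g{i}": "b1" for i in range(5)}
        table = secreted_census(assigns, signal, bins)
        row = table.set_index(["bin_id", "category"]).loc[("b1", "peptidase")]
        assert row.total == 5
        assert row.secreted == 3  # g4 absent from signal table -> False

    def test_no_signal_calls_all_zero(self):
        assigns = [assign("g1", "peptidase", "M01"),
                   assign("g2", "lipase", "abH04")]
        table = secreted_census(assigns, {}, {"g1": "b", "g2": "b"})
        assert (table.secreted == 0).all()

    def test_secreted_never_exceeds_total_random(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 40))
            assigns = [
                assign(f"g{i}",
                       ("peptidase", "lipase", "cazyme")[rng.integers(3)],
                       "X")
                for i in range(n)
            ]
            signal = {f"g{i}": bool(rng.integers(2)) for i in range(n)}
            bins = {f"g{i}": f"b{rng.integers(4)}" for i in range(n)}
            table = secreted_census(assigns, signal, bins)
            assert (table.secreted <= table.total).all()


class TestHighlyExpressed:
    def test_hand_arithmetic(self):
        rpkm = {"g1": 1.0, "g2": 2.0, "g3": 3.0, "g4": 4.0, "g5": 5.0}
        he = highly_expressed(rpkm)
        assert he.median == 3.0
        assert he.genes == {"g4", "g5"}
        assert he.fold["g4"] == pytest.approx(4 / 3)
        assert he.fold["g5"] == pytest.approx(5 / 3)

    def test_constant_vector_gives_empty_set(self):
        he = highly_expressed({f"g{i}": 7.0 for i in range(9)})
        assert he.genes == set()

    def test_zero_median_reports_infinite_fold(self):
        he = highly_expressed({"g1": 0.0, "g2": 0.0, "g3": 5.0})
        assert he.genes == {"g3"}
        assert math.isinf(he.fold["g3"])

    def test_fold_reported_relative_to_median(self):
        # e.g. an adhesion gene at 3x the bin median activity
        rpkm = {"adh": 6.0, "a": 1.0, "b": 2.0, "c": 2.0, "d": 3.0}
        he = highly_expressed(rpkm)
        assert he.fold["adh"] == pytest.approx(3.0)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValidationError):
            highly_expressed({})

    def test_strict_median_bound_on_distinct_values(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 60))
            values = rng.permutation(n).astype(float)
            he = highly_expressed({f"g{i}": v
                                   for i, v in enumerate(values)})
            assert len(he.genes) < n
            assert len(he.genes) <= n // 2


class TestCensusTable:
    def test_peptidase_type_from_family_code(self):
        assert peptidase_type("M16B") == "M"
        assert peptidase_type("S08A") == "S"
        assert peptidase_type("C01A") == "C"
        assert peptidase_type("T01A") == "other"

    def test_type_breakdown_sums_to_total(self, rng):
        labels = ["M01", "S08A", "C01A", "T01A", "A08"]
        assigns = [assign(f"g{i}", "peptidase",
                          labels[rng.integers(len(labels))])
                   for i in range(60)]
        bins = {f"g{i}": f"b{rng.integers(3)}" for i in range(60)}
        table = census_table(assigns, {}, bins, ["b0", "b1", "b2"])
        total = (table.peptidase_M + table.peptidase_S + table.peptidase_C
                 + table.peptidase_other)
        assert (total == table.peptidase_total).all()

    def test_row_order_invariance(self, rng):
        labels = ["M01", "S08A", "GH13", "SusC", "PF01103"]
        kinds = ["peptidase", "peptidase", "cazyme", "transporter",
                 "adhesion"]
        assigns = [assign(f"g{i}", kinds[i % 5], labels[i % 5])
                   for i in range(40)]
        bins = {f"g{i}": "b0" for i in range(40)}
        signal = {f"g{i}": bool(i % 2) for i in range(40)}
        t1 = census_table(assigns, signal, bins, ["b0"])
        shuffled = list(assigns)
        rng.shuffle(shuffled)
        t2 = census_table(shuffled, signal, bins, ["b0"])
        assert t1.equals(t2)

    def test_study_community_counts_match_planted(self, study_community,
                                                  tmp_path):
        from aadeg.pipeline import RunConfig, run_pipeline
        study_community.write(tmp_path)
        bundle = run_pipeline(RunConfig.for_community_dir(
            tmp_path, stages=("census",)))
        table = bundle["census"].set_index("bin_id")
        for bin_id, truth in study_community.truth[
                "category_counts"].items():
            row = table.loc[bin_id]
            assert row.peptidase_total == truth["peptidase_total"]
            assert row.secreted_peptidases == truth["secreted_peptidases"]
            assert row.adhesion_genes == truth["adhesion_genes"]
            assert row.susC_genes == truth["susC_genes"]
            assert row.glycoside_hydrolases == truth["glycoside_hydrolases"]
            assert row.lipases == truth["lipases"]
            assert row.secreted_peptidases <= row.peptidase_total
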