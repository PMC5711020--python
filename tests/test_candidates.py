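from itertools import product

import numpy as np
import pandas as pd
import pytest

from congenicqtl import IntervalSet, bh_fdr, de_filter, overlap_evidence
from congenicqtl.intervals import Interval
from congenicqtl.sequential import Qtl, QtlModel

from oracles import bh_qvalues

MB = 1_000_000


class TestBhFdr:
    def test_hand_computed_example(self):
        got = bh_fdr([0.01, 0.02, 0.03])
        np.testing.assert_allclose(got, [0.03, 0.03, 0.03])

    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.04]), [0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_step_up_definition(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 25)
        np.testing.assert_allclose(bh_fdr(p), bh_qvalues(p), rtol=1e-12)

    def test_q_at_least_p_and_monotone_in_ranking(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, 40)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def expression_frame(entries):
    return pd.DataFrame(
        [
            {
                "gene_id": g,
                "chrom": "chr9",
                "start": start,
                "end": start + 10_000,
                "log2fc": fc,
                "p_value": p,
            }
            for g, start, fc, p in entries
        ]
    )


class TestDeFilter:
    def test_fold_change_alone_passes_and_reproduces(self):
        # large fold change, hopeless p-value: the OR rule passes it
        exp = {
            "e1": expression_frame([("gA", 50 * MB, 0.7, 0.9), ("gB", 50 * MB, 0.1, 0.9)]),
            "e2": expression_frame([("gA", 50 * MB, 0.8, 0.8), ("gB", 50 * MB, 0.0, 0.7)]),
        }
        res = de_filter(exp)
        assert res.reproducible == {"gA"}

    def test_gene_passing_in_one_experiment_is_not_reproducible(self):
        exp = {
            "e1": expression_frame([("gA", 50 * MB, 0.7, 0.9)]),
            "e2": expression_frame([("gA", 50 * MB, 0.1, 0.9)]),
        }
        assert de_filter(exp).reproducible == set()

    def test_downregulated_gene_passes_both_subfilters(self):
        exp = {
            "e1": expression_frame([("gA", 50 * MB, -0.6, 0.001), ("gB", 50 * MB, 0.0, 0.9)]),
            "e2": expression_frame([("gA", 50 * MB, -0.7, 0.002), ("gB", 50 * MB, 0.0, 0.9)]),
        }
        res = de_filter(exp, require_both_subfilters=True)
        assert res.reproducible == {"gA"}

    def test_region_restriction_drops_outside_genes(self):
        exp = {
            "e1": expression_frame([("gIn", 50 * MB, 0.9, 0.9), ("gOut", 90 * MB, 0.9, 0.9)]),
            "e2": expression_frame([("gIn", 50 * MB, 0.9, 0.9), ("gOut", 90 * MB, 0.9, 0.9)]),
        }
        res = de_filter(exp, region=IntervalSet([(42 * MB, 58 * MB)]))
        assert res.reproducible == {"gIn"}

    def test_mismatched_universes_intersected_with_warning(self):
        exp = {
            "e1": expression_frame([("gA", 50 * MB, 0.7, 0.9), ("gC", 50 * MB, 0.7, 0.9)]),
            "e2": expression_frame([("gA", 50 * MB, 0.7, 0.9)]),
        }
        with pytest.warns(UserWarning, match="mismatched"):
            res = de_filter(exp)
        assert res.reproducible == {"gA"}

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(4)
        entries = [
            (f"g{i}", (40 + i) * MB, float(rng.normal(0, 0.6)), float(rng.uniform(0, 1)))
            for i in range(30)
        ]
        exp = {"e1": expression_frame(entries), "e2": expression_frame(entries)}
        loose = de_filter(exp, fc_threshold_log2=0.3, q_threshold=0.2)
        tight = de_filter(exp, fc_threshold_log2=0.58, q_threshold=0.05)
        assert tight.reproducible <= loose.reproducible

    def test_single_experiment_rejected(self):
        with pytest.raises(ValueError, match="two experiments"):
            de_filter({"e1": expression_frame([("g", MB, 0.0, 1.0)])})


def model_with(intervals):
    qtls = tuple(
        Qtl(Interval(s, e), "+", (Interval(s, e),), ()) for s, e in intervals
    )
    return QtlModel(qtls, len(qtls), sum(e - s + 1 for s, e in intervals))


class TestOverlapEvidence:
    def gene_table(self, genes):
        return pd.DataFrame(
            [
                {"gene_id": g, "chrom": "chr9", "start": s, "end": s + 10_000}
                for g, s in genes
            ]
        )

    def test_flag_combinations_counted_like_set_enumeration(self):
        rng = np.random.default_rng(6)
        genes = [(f"g{i}", (43 + i) * MB) for i in range(10)]
        flag_rows = []
        for g, _ in genes:
            flag_rows.append(
                {
                    "gene_id": g,
                    "differential_expression": bool(rng.integers(2)),
                    "missense_variant": bool(rng.integers(2)),
                    "human_gwas_orthologue": bool(rng.integers(2)),
                }
            )
        flags = pd.DataFrame(flag_rows)
        model = model_with([(42 * MB, 56 * MB)])
        table = overlap_evidence(model, self.gene_table(genes), flags)
        inside = [g for g, s in genes if 42 * MB <= s <= 56 * MB]
        assert set(table.genes["gene_id"]) == set(inside)
        # brute-force recount of every 2^3 cell
        for combo in product((False, True), repeat=3):
            expected = sum(
                1
                for row in flag_rows
                if row["gene_id"] in inside
                and (
                    row["differential_expression"],
                    row["missense_variant"],
                    row["human_gwas_orthologue"],
                )
                == combo
            )
            assert table.intersection_counts[combo] == expected

    def test_gene_with_two_evidence_lines_lands_in_two_way_cell(self):
        genes = self.gene_table([("gX", 50 * MB)])
        flags = pd.DataFrame(
            [{"gene_id": "gX", "differential_expression": True, "missense_variant": True,
              "human_gwas_orthologue": False}]
        )
        table = overlap_evidence(model_with([(48 * MB, 54 * MB)]), genes, flags)
        assert table.count(True, True, False) == 1

    def test_empty_model_gives_empty_table(self):
        table = overlap_evidence(
            model_with([]), self.gene_table([("g", 50 * MB)]), pd.DataFrame(columns=["gene_id"])
        )
        assert table.genes.empty
        assert sum(table.intersection_counts.values()) == 0

    def test_missing_flags_default_false(self):
        genes = self.gene_table([("gX", 50 * MB)])
        flags = pd.DataFrame([{"gene_id": "gX", "missense_variant": True}])
        table = overlap_evidence(model_with([(48 * MB, 54 * MB)]), genes, flags)
        assert table.count(False, True, False) == 1
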