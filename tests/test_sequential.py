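import numpy as np
import pytest

from congenicqtl import (
    IntervalSet,
    build_mst,
    default_config,
    infer_qtl_model,
    prepare_phenotypes,
    qtl_effect_table,
    refine_qtl,
    run_comparisons,
    simulate_panel,
)
from congenicqtl.intervals import Interval
from congenicqtl.sequential import (
    ComparisonOutcome,
    InconsistentComparisonsError,
    Qtl,
    QtlModel,
)

from oracles import enumerate_minimal_qtl_assignments, minimum_spanning_weight

MB = 1_000_000


def mb_set(*pairs):
    return IntervalSet([(int(a * MB), int(b * MB)) for a, b in pairs])


class TestBuildMst:
    def test_nested_strains_form_a_path_from_host(self):
        regions = {
            "s10": mb_set((1, 10)),
            "s20": mb_set((1, 20)),
            "s30": mb_set((1, 30)),
        }
        g = build_mst(regions)
        assert set(map(frozenset, [(e[0], e[1]) for e in g.mst_edges])) == {
            frozenset({"host", "s10"}),
            frozenset({"s10", "s20"}),
            frozenset({"s20", "s30"}),
        }
        assert g.traversal == [("host", "s10"), ("s10", "s20"), ("s20", "s30")]

    def test_disjoint_donor_fragments_branch_at_host(self):
        regions = {
            "left": mb_set((1, 10)),
            "left_long": mb_set((1, 25)),
            "right": mb_set((80, 95)),
            "right_long": mb_set((80, 110)),
        }
        g = build_mst(regions)
        edge_sets = {frozenset((e[0], e[1])) for e in g.mst_edges}
        assert frozenset({"host", "left"}) in edge_sets
        assert frozenset({"host", "right"}) in edge_sets
        assert frozenset({"left", "left_long"}) in edge_sets
        assert frozenset({"right", "right_long"}) in edge_sets

    def test_single_strain_hangs_off_host(self):
        g = build_mst({"only": mb_set((5, 9))})
        assert g.mst_edges == [("host", "only", 4 * MB + 1)]
        assert g.traversal == [("host", "only")]

    def test_duplicate_regions_merge_with_warning(self):
        with pytest.warns(UserWarning, match="merged"):
            g = build_mst({"a": mb_set((1, 10)), "b": mb_set((1, 10))})
        assert g.members["a"] == ["a", "b"]
        assert "b" not in g.nodes

    @pytest.mark.parametrize("seed", range(8))
    def test_mst_weight_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n_strains = int(rng.integers(3, 6))
        regions = {}
        for i in range(n_strains):
            s = int(rng.integers(1, 900))
            regions[f"s{i}"] = IntervalSet([(s, s + int(rng.integers(0, 100)))])
        g = build_mst(regions)
        nodes = g.nodes

        def weight(i, j):
            return (
                g.regions[nodes[i]].symmetric_difference(g.regions[nodes[j]]).total_length
            )

        best = minimum_spanning_weight(len(nodes), weight)
        assert sum(w for _, _, w in g.mst_edges) == best


def outcome(g1, g2, verdict, diff: IntervalSet, p=None):
    if p is None:
        p = 0.001 if verdict != "equal" else 0.5
    return ComparisonOutcome(g1, g2, 20, 20, 0.0, 0.0, p, verdict, diff)


class TestInference:
    def test_single_qtl_in_the_outermost_only_bin(self):
        """Three nested strains; only the outermost differs from host:
        the QTL must sit in the segment only the outermost carries."""
        regions = {
            "host": IntervalSet(),
            "s1": mb_set((1, 10)),
            "s2": mb_set((1, 20)),
            "s3": mb_set((1, 30)),
        }
        outcomes = [
            outcome("s1", "host", "equal", regions["s1"]),
            outcome("s2", "s1", "equal", regions["s2"] ^ regions["s1"]),
            outcome("s3", "s2", "greater", regions["s3"] ^ regions["s2"]),
        ]
        inf = infer_qtl_model(outcomes, regions)
        assert len(inf.models) == 1
        model = inf.best
        assert model.n_qtls == 1
        assert model.qtls[0].sign == "+"
        assert model.qtls[0].interval.start == 20 * MB + 1

    def test_masked_opposing_pair_resolved_by_substrain(self):
        """A fragment spanning two bins looks null against host, yet the
        sub-fragment covering only the first bin raises the trait: the
        minimal explanation is two opposing QTLs, flagged masked."""
        regions = {
            "host": IntervalSet(),
            "wide": mb_set((1, 20)),
            "sub": mb_set((1, 10)),
        }
        outcomes = [
            outcome("wide", "host", "equal", regions["wide"]),
            outcome("sub", "host", "greater", regions["sub"]),
        ]
        inf = infer_qtl_model(outcomes, regions)
        model = inf.best
        assert model.n_qtls == 2
        signs = {(q.interval.start, q.sign) for q in model.qtls}
        assert (1 * MB, "+") in signs
        assert (10 * MB + 1, "-") in signs
        assert model.masked_comparisons == (0,)

    def test_all_equal_comparisons_give_empty_model(self):
        regions = {"host": IntervalSet(), "s": mb_set((1, 10))}
        inf = infer_qtl_model([outcome("s", "host", "equal", regions["s"])], regions)
        assert inf.best.n_qtls == 0

    def test_unsatisfiable_comparisons_raise(self):
        regions = {"host": IntervalSet(), "s": mb_set((1, 10))}
        # significant difference with an empty difference region
        bad = [outcome("s", "s", "greater", IntervalSet())]
        with pytest.raises(InconsistentComparisonsError):
            infer_qtl_model(bad, regions, max_qtls=2)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_enumeration(self, seed):
        """Random strain layouts + verdicts derived from a random truth:
        the search must find assignments identical to an independent
        enumeration oracle (same minimal active-bin count, same set)."""
        rng = np.random.default_rng(100 + seed)
        n_strains = int(rng.integers(2, 5))
        regions = {"host": IntervalSet()}
        for i in range(n_strains):
            s = int(rng.integers(1, 500))
            regions[f"s{i}"] = IntervalSet([(s, s + int(rng.integers(10, 300)))])
        from congenicqtl import atomic_bins

        bins = atomic_bins([r for r in regions.values() if r])
        truth = {
            i: int(rng.choice([-1, 0, 0, 1])) for i in range(len(bins))
        }
        names = sorted(regions)
        outcomes = []
        for a_i in range(len(names)):
            for b_i in range(a_i + 1, len(names)):
                g1, g2 = names[a_i], names[b_i]
                diff = regions[g1] ^ regions[g2]
                net = sum(
                    truth[i] * (1 if regions[g1].contains(b.start) else -1)
                    for i, b in enumerate(bins)
                    if diff.contains(b.start)
                )
                verdict = "greater" if net > 0 else "less" if net < 0 else "equal"
                outcomes.append(outcome(g1, g2, verdict, diff))
        inf = infer_qtl_model(outcomes, regions, max_qtls=6)

        comparisons = []
        for oc in outcomes:
            touched = [
                (i, 1 if regions[oc.group_1].contains(b.start) else -1)
                for i, b in enumerate(bins)
                if oc.difference_region.contains(b.start)
            ]
            comparisons.append((oc.verdict, touched))
        k_oracle, assignments = enumerate_minimal_qtl_assignments(
            len(bins), comparisons
        )
        assert inf.best.n_active_bins == k_oracle
        got = set()
        for model in inf.models:
            items = []
            for q in model.qtls:
                for b in q.bins:
                    items.append((bins.index(b), 1 if q.sign == "+" else -1))
            got.add(frozenset(items))
        best_key = min(
            (len(_merged_qtls(a, bins)), sum(bins[i].length for i, _ in a))
            for a in assignments
        )
        oracle_minimal = {
            a
            for a in assignments
            if (len(_merged_qtls(a, bins)), sum(bins[i].length for i, _ in a)) == best_key
        }
        assert got == oracle_minimal


def _merged_qtls(assignment, bins):
    """Merge adjacent same-sign active bins, mirroring model assembly."""
    items = sorted(assignment)
    merged = []
    for i, sign in items:
        if merged and merged[-1][1] == sign and bins[merged[-1][0][-1]].end + 1 == bins[i].start:
            merged[-1][0].append(i)
        else:
            merged.append(([i], sign))
    return merged


class TestRefine:
    def make_model(self, start, end, sign="+"):
        iv = Interval(start, end)
        return QtlModel((Qtl(iv, sign, (iv,), ()),), 1, iv.length)

    def test_ten_mb_window_centred_on_anchor(self):
        model = self.make_model(58_262_383, 124_595_110)
        refined = refine_qtl(model, anchor_bp=113_915_010, flank_mb=10)
        q = refined.qtls[0]
        assert (q.interval.start, q.interval.end) == (108_915_010, 118_915_010)
        assert q.refined

    def test_window_clipped_to_original_interval(self):
        model = self.make_model(100 * MB, 130 * MB)
        refined = refine_qtl(model, anchor_bp=102 * MB, flank_mb=10)
        assert refined.qtls[0].interval == Interval(100 * MB, 107 * MB)

    def test_flank_wider_than_interval_leaves_it_unchanged(self):
        model = self.make_model(100 * MB, 130 * MB)
        refined = refine_qtl(model, anchor_bp=115 * MB, flank_mb=100)
        assert refined.qtls[0].interval == Interval(100 * MB, 130 * MB)

    def test_zero_flank_collapses_to_the_anchor(self):
        model = self.make_model(100 * MB, 130 * MB)
        refined = refine_qtl(model, anchor_bp=115 * MB, flank_mb=0)
        assert refined.qtls[0].interval == Interval(115 * MB, 115 * MB)

    def test_anchor_outside_every_interval_rejected(self):
        model = self.make_model(100 * MB, 130 * MB)
        with pytest.raises(ValueError, match="no QTL interval"):
            refine_qtl(model, anchor_bp=50 * MB)

    def test_narrow_interval_left_alone(self):
        model = self.make_model(100 * MB, 105 * MB)
        refined = refine_qtl(model, anchor_bp=102 * MB, flank_mb=2)
        assert refined.qtls[0].interval == Interval(100 * MB, 105 * MB)


class TestEndToEnd:
    def test_null_panel_comparisons_are_mostly_equal(self):
        cfg = default_config(seed=77, qtls=())
        panel, _ = simulate_panel(cfg)
        prepared, _ = prepare_phenotypes(panel)
        with pytest.warns(UserWarning, match="merged"):
            graph = build_mst(prepared.strain_donor_regions())
        outcomes = run_comparisons(graph, prepared)
        n_equal = sum(oc.verdict == "equal" for oc in outcomes)
        assert n_equal >= len(outcomes) - 2

    def test_four_qtl_recovery_on_the_default_panel(self, prepared_default_panel):
        prepared, truth, _ = prepared_default_panel
        with pytest.warns(UserWarning, match="merged"):
            graph = build_mst(prepared.strain_donor_regions())
        outcomes = run_comparisons(graph, prepared)
        inf = infer_qtl_model(outcomes, graph.regions)
        model = inf.best
        assert model.n_qtls == 4
        assert model.signs() == ("+", "+", "-", "+")
        for q, planted in zip(model.qtls, truth["qtls"]):
            assert q.interval.contains(planted["pos_bp"])
            assert q.support  # every QTL backed by at least one comparison
        # dropping every strain with a breakpoint between QTL2 and QTL3
        # leaves the opposing pair inside one bin: the model collapses
        pruned_regions = {
            n: r
            for n, r in graph.regions.items()
            if n not in ("3", "1.1", "3.1.1", "3.1.2", "host")
        }
        pruned_graph = build_mst(pruned_regions)
        pruned = run_comparisons(pruned_graph, prepared)
        pruned_inf = infer_qtl_model(pruned, pruned_graph.regions)
        assert pruned_inf.best.n_qtls <= 3

    def test_effect_table_reports_both_genotypes_per_qtl(self, prepared_default_panel):
        prepared, truth, _ = prepared_default_panel
        with pytest.warns(UserWarning, match="merged"):
            graph = build_mst(prepared.strain_donor_regions())
        outcomes = run_comparisons(graph, prepared)
        model = infer_qtl_model(outcomes, graph.regions).best
        table = qtl_effect_table(prepared, model)
        assert len(table) == 2 * model.n_qtls
        for q in model.qtls:
            sub = table[table["qtl"] == f"{q.interval}{q.sign}"].set_index("genotype")
            gap = sub.loc["H", "ls_mean"] - sub.loc["A", "ls_mean"]
            assert (gap > 0) == (q.sign == "+")
            assert (sub["ci_low"] < sub["ls_mean"]).all()
            assert (sub["ls_mean"] < sub["ci_high"]).all()
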