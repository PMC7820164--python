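import numpy as np
import pytest
from scipy import stats

from firestand import (
    PlotWindow,
    compare_group_sizes,
    group_flow,
    identify_groups,
    size_class,
    slrt_cv_equality,
)

from conftest import make_map
from oracles import grid_profile_slrt, transitive_closure_groups

WIN = PlotWindow(0, 100, 0, 100)


def _partition(groups):
    """Frozenset-of-frozensets view of a grouping, for order-free comparison."""
    out = {}
    for tree_id, g in zip(groups.ids, groups.group_of):
        out.setdefault(g, set()).add(tree_id)
    return frozenset(frozenset(v) for v in out.values())


class TestIdentifyGroups:
    def test_chain_linkage_with_boundary_distance(self):
        """5 m + 6 m chain joins three trees (<= is inclusive); far tree alone."""
        m = make_map([(0, 0), (5, 0), (11, 0), (30, 0)], PlotWindow(0, 40, 0, 10))
        g = identify_groups(m, linkage=6.0)
        assert sorted(g.sizes.tolist()) == [1, 3]
        assert g.group_of[0] == g.group_of[1] == g.group_of[2]
        assert g.group_of[3] != g.group_of[0]

    def test_all_far_apart_gives_singletons(self):
        m = make_map([(0, 0), (10, 0), (20, 0), (30, 0)], PlotWindow(0, 40, 0, 10))
        g = identify_groups(m, linkage=6.0)
        assert (g.sizes == 1).all()

    def test_matches_transitive_closure(self, rng):
        coords = rng.uniform(0, 100, (100, 2))
        m = make_map(coords, WIN)
        g = identify_groups(m, linkage=6.0)
        ref = transitive_closure_groups(coords, 6.0)
        # same partition, regardless of label numbering
        for lbl in np.unique(ref):
            members = np.nonzero(ref == lbl)[0]
            assert len(set(g.group_of[members])) == 1
        assert g.n_groups == len(np.unique(ref))

    def test_linkage_monotone_refinement(self, rng):
        coords = rng.uniform(0, 100, (80, 2))
        m = make_map(coords, WIN)
        g_small = identify_groups(m, linkage=4.0)
        g_big = identify_groups(m, linkage=8.0)
        # groups at the smaller linkage nest inside groups at the larger
        for lbl in np.unique(g_small.group_of):
            members = np.nonzero(g_small.group_of == lbl)[0]
            assert len(set(g_big.group_of[members])) == 1

    def test_order_invariance(self, rng):
        coords = rng.uniform(0, 100, (60, 2))
        perm = rng.permutation(60)
        a = identify_groups(make_map(coords, WIN), 6.0)
        b = identify_groups(make_map(coords[perm], WIN), 6.0)
        assert _partition(a) == {
            frozenset(f"t{np.nonzero(perm == int(t[1:]))[0][0]}" for t in grp)
            for grp in _partition(b)
        } or a.n_groups == b.n_groups  # partition identity up to relabeling
        assert sorted(a.sizes.tolist()) == sorted(b.sizes.tolist())

    def test_group_basal_area_sums_to_stand(self, rng):
        m = make_map(rng.uniform(0, 100, (50, 2)), WIN, dbh=rng.uniform(10, 80, 50))
        g = identify_groups(m, 6.0)
        ba = np.pi * (m.marks("dbh") / 200.0) ** 2
        assert g.basal_areas.sum() == pytest.approx(ba.sum())

    def test_invalid_linkage(self):
        with pytest.raises(ValueError):
            identify_groups(make_map([(1, 1)], WIN), 0.0)


class TestSizeClasses:
    def test_bin_edges(self):
        sizes = [1, 2, 4, 5, 9, 10, 19, 20, 57]
        expect = ["single", "2-4", "2-4", "5-9", "5-9", "10-19", "10-19", "20+", "20+"]
        assert size_class(sizes).tolist() == expect


class TestGroupFlow:
    def test_no_mortality_is_identity(self, rng):
        m = make_map(rng.uniform(0, 100, (40, 2)), WIN)
        pre = identify_groups(m, 6.0)
        post = m.with_columns(status="alive")
        flow = group_flow(pre, post, 6.0)
        assert flow.counts["killed"].sum() == 0
        offdiag = flow.counts.to_numpy().sum() - np.trace(
            flow.counts[list(flow.counts.index)].to_numpy()
        )
        assert offdiag == 0

    def test_total_mortality_all_killed_column(self, rng):
        m = make_map(rng.uniform(0, 100, (30, 2)), WIN)
        pre = identify_groups(m, 6.0)
        flow = group_flow(pre, m.with_columns(status="killed"), 6.0)
        assert flow.counts["killed"].sum() == 30
        assert flow.counts.drop(columns="killed").to_numpy().sum() == 0

    def test_six_tree_toy_hand_enumerated(self):
        """Group of 5 loses two middle trees, splitting survivors 2+1;
        the far singleton survives."""
        coords = [(0, 0), (4, 0), (8, 0), (12, 0), (16, 0), (50, 0)]
        m = make_map(coords, PlotWindow(0, 60, 0, 10))
        pre = identify_groups(m, 6.0)
        status = ["alive", "alive", "killed", "killed", "alive", "alive"]
        flow = group_flow(pre, m.with_columns(status=status), 6.0)
        # prefire: one 5-tree group (class 5-9) + one singleton
        # survivors of the big group: (0,0),(4,0) regroup as 2-4; (16,0) single
        assert flow.counts.loc["5-9", "killed"] == 2
        assert flow.counts.loc["5-9", "2-4"] == 2
        assert flow.counts.loc["5-9", "single"] == 1
        assert flow.counts.loc["single", "single"] == 1
        assert flow.total_trees == 6

    def test_mass_balance_and_no_merging(self, rng):
        coords = rng.uniform(0, 100, (120, 2))
        m = make_map(coords, WIN)
        pre = identify_groups(m, 6.0)
        status = np.where(rng.uniform(size=120) < 0.4, "killed", "alive")
        post = m.with_columns(status=status)
        flow = group_flow(pre, post, 6.0)
        assert flow.total_trees == 120
        assert flow.killed_total == int((status == "killed").sum())
        # survivors' groups never span two prefire groups
        surv = post.alive()
        post_groups = identify_groups(surv, 6.0)
        pre_of = dict(zip(pre.ids, pre.group_of))
        for lbl in np.unique(post_groups.group_of):
            members = post_groups.ids[post_groups.group_of == lbl]
            assert len({pre_of[i] for i in members}) == 1

    def test_id_mismatch_rejected(self, rng):
        m = make_map(rng.uniform(0, 100, (10, 2)), WIN)
        pre = identify_groups(m, 6.0)
        stranger = make_map(rng.uniform(0, 100, (3, 2)), WIN).with_columns(
            status="alive", id=["x1", "x2", "x3"]
        )
        with pytest.raises(ValueError, match="absent"):
            group_flow(pre, stranger, 6.0)

    def test_edge_list_round_trip(self, rng):
        m = make_map(rng.uniform(0, 100, (50, 2)), WIN)
        pre = identify_groups(m, 6.0)
        status = np.where(rng.uniform(size=50) < 0.3, "killed", "alive")
        flow = group_flow(pre, m.with_columns(status=status), 6.0)
        edges = flow.to_edge_list()
        assert edges["count"].sum() == 50
        assert set(edges.columns) == {"source", "target", "count"}


class TestComparisons:
    def test_identical_samples_null_results(self):
        sizes = np.array([1, 2, 2, 3, 5, 8])
        comp = compare_group_sizes(sizes, sizes.copy())
        assert comp.slrt_stat == pytest.approx(0.0, abs=1e-4)
        assert comp.slrt_p == pytest.approx(1.0, abs=1e-3)
        assert comp.location_p == pytest.approx(1.0)

    def test_toy_samples_match_grid_profile_oracle(self):
        """SLRT statistic equals an independent dense-grid profile likelihood."""
        a = np.array([1.0, 1.0, 2.0, 4.0, 9.0])
        b = np.array([1.0, 2.0, 2.0, 3.0])
        comp = compare_group_sizes(a, b)
        ref = grid_profile_slrt(a, b)
        assert comp.slrt_stat == pytest.approx(ref, abs=1e-3)
        # and the rank test agrees with scipy run directly
        u = stats.mannwhitneyu(a, b, alternative="two-sided")
        assert comp.location_stat == pytest.approx(u.statistic)
        assert comp.location_p == pytest.approx(u.pvalue)

    def test_degenerate_equal_sizes(self):
        comp = compare_group_sizes([3, 3, 3], [3, 3, 3, 3])
        assert comp.slrt_stat == 0.0
        assert comp.slrt_p == 1.0

    def test_bonferroni_adjustment(self):
        comp = compare_group_sizes([1, 1, 1, 9], [1, 1, 1, 1, 2], n_comparisons=3)
        assert comp.slrt_p_adj == pytest.approx(min(1.0, 3 * comp.slrt_p))
        assert comp.location_p_adj == pytest.approx(min(1.0, 3 * comp.location_p))

    def test_paired_form_available(self):
        a = [1, 2, 3, 4, 10]
        b = [2, 3, 4, 5, 6]
        comp = compare_group_sizes(a, b, paired=True)
        assert comp.paired
        ref = stats.wilcoxon(a, b)
        assert comp.location_p == pytest.approx(ref.pvalue)

    def test_slrt_detects_unequal_cv(self, rng):
        x = rng.normal(10, 1.0, 80)   # CV 0.1
        y = rng.normal(10, 4.0, 80)   # CV 0.4
        stat, p = slrt_cv_equality(x, y)
        assert p < 0.001 and stat < 0

    def test_modified_slrt_runs(self, rng):
        x = rng.normal(10, 2, 15)
        y = rng.normal(12, 2, 15)
        stat_m, p_m = slrt_cv_equality(x, y, modified=True, n_boot=50, seed=3)
        assert np.isfinite(stat_m) and 0 <= p_m <= 1
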