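import numpy as np
import pytest

from firestand import (
    PlotWindow,
    bivariate_pair_correlation,
    estimate_intensity,
    mark_variogram,
    mortality_difference_statistics,
    pair_correlation,
    r_mark_correlation,
)
from firestand.spatial_stats import points_lambda

from conftest import csr_map, make_map
from oracles import (
    naive_bivariate_pcf,
    naive_mark_stats,
    naive_pair_correlation,
)

WIN = PlotWindow(0, 100, 0, 100)


class TestIntensity:
    def test_single_interior_point_mass_conserved(self):
        m = make_map([(50, 50)], WIN)
        field = estimate_intensity(m, bandwidth=20)
        assert field.integral == pytest.approx(1.0, abs=1e-3)

    def test_many_points_mass_conserved(self, rng):
        m = csr_map(rng, 0.005, WIN)
        field = estimate_intensity(m, bandwidth=20)
        assert field.integral == pytest.approx(m.n, abs=0.1)

    def test_corner_point_renormalized(self):
        """Corner point: integral still 1, peak ~4x the interior peak."""
        interior = estimate_intensity(make_map([(50, 50)], WIN), bandwidth=20)
        corner = estimate_intensity(make_map([(0.5, 0.5)], WIN), bandwidth=20)
        assert corner.integral == pytest.approx(1.0, abs=1e-3)
        ratio = corner.values.max() / interior.values.max()
        assert 3.5 < ratio < 4.5

    def test_nonpositive_bandwidth(self):
        with pytest.raises(ValueError):
            estimate_intensity(make_map([(1, 1)], WIN), bandwidth=0)

    def test_leave_one_out_removes_self_peak(self):
        m = make_map([(50, 50), (20, 20)], WIN)
        with_self = points_lambda(m, bandwidth=20, leave_one_out=False)
        loo = points_lambda(m, bandwidth=20, leave_one_out=True)
        assert np.all(loo < with_self)


class TestPairCorrelation:
    def test_two_point_hand_oracle(self):
        """Exactly 2 points 5 m apart: hand-evaluated estimator value."""
        win = PlotWindow(0, 30, 0, 30)
        m = make_map([(10.0, 10.0), (15.0, 10.0)], win)
        g = pair_correlation(m, r_max=15, ring=1)
        # distance 5.0 lies on a bin edge -> lower ring (4, 5], center 4.5
        T = (30 - 5) * (30 - 0)          # translation overlap area
        lam2 = 2 * 1 / (900.0**2)        # n(n-1)/|W|^2
        ring_area = np.pi * (25 - 16)
        expected = (2 / T) / lam2 / ring_area
        assert g.values[4] == pytest.approx(expected, rel=1e-12)
        others = np.delete(g.values, 4)
        assert np.all(others == 0.0)

    def test_lattice_has_empty_small_rings(self):
        pts = [(x, y) for x in range(5, 100, 10) for y in range(5, 100, 10)]
        g = pair_correlation(make_map(pts, WIN), r_max=15, ring=1)
        assert np.all(g.values[:9] == 0.0)  # rings entirely below 10 m

    def test_matches_naive_oracle(self, rng):
        m = csr_map(rng, 0.008, WIN)
        g = pair_correlation(m, r_max=15, ring=1)
        ref = naive_pair_correlation(m.coords, WIN)
        np.testing.assert_allclose(g.values, ref, rtol=1e-10)

    def test_translation_invariance(self, rng):
        coords = rng.uniform(0, 100, (60, 2))
        g1 = pair_correlation(make_map(coords, WIN))
        g2 = pair_correlation(
            make_map(coords + [250.0, -40.0], PlotWindow(250, 350, -40, 60))
        )
        np.testing.assert_allclose(g1.values, g2.values, rtol=1e-10)

    def test_inhomogeneous_estimator_calibrated_on_true_intensity(self):
        """Mean inhom g-hat over seeds is ~1 under inhomogeneous Poisson
        with the true (linear-gradient) intensity plugged in."""
        win = PlotWindow(0, 100, 0, 100)
        lam = lambda x: 0.01 + 0.06 * x / 100.0  # trees/m^2, gradient in x
        vals = []
        for s in range(40):
            r = np.random.default_rng(s)
            n_prop = r.poisson(0.07 * 1e4)
            xs = r.uniform(0, 100, n_prop)
            ys = r.uniform(0, 100, n_prop)
            keep = r.uniform(0, 0.07, n_prop) < lam(xs)
            m = make_map(np.column_stack([xs[keep], ys[keep]]), win)
            vals.append(pair_correlation(m, intensity=lam(m.coords[:, 0])).values)
        gbar = np.mean(vals, axis=0)
        assert np.all(np.abs(gbar[2:] - 1.0) < 0.05)  # bias < 5% at r >= 2 m

    def test_oversized_r_max_warns(self, rng):
        m = csr_map(rng, 0.01, PlotWindow(0, 40, 0, 40))
        with pytest.warns(UserWarning, match="r_max"):
            pair_correlation(m, r_max=30)


class TestBivariate:
    def test_reduces_to_univariate(self, rng):
        m = csr_map(rng, 0.01, WIN)
        every = np.ones(m.n, dtype=bool)
        g12 = bivariate_pair_correlation(m, every, every)
        g = pair_correlation(m)
        np.testing.assert_array_equal(g12.values, g.values)

    def test_two_point_toy(self):
        win = PlotWindow(0, 30, 0, 30)
        m = make_map([(10.0, 10.0), (15.0, 10.0)], win)
        g12 = bivariate_pair_correlation(
            m, np.array([True, False]), np.array([False, True])
        )
        T = (30 - 5) * 30
        lam2 = 1 * 1 / 900.0**2
        expected = (1 / T) / lam2 / (np.pi * (25 - 16))
        assert g12.values[4] == pytest.approx(expected, rel=1e-12)

    def test_independent_superposition_near_one(self):
        vals = []
        for s in range(20):
            r = np.random.default_rng(s)
            n1, n2 = r.poisson(80), r.poisson(80)
            coords = np.vstack(
                [r.uniform(0, 100, (n1, 2)), r.uniform(0, 100, (n2, 2))]
            )
            m = make_map(coords, WIN)
            t1 = np.arange(m.n) < n1
            g12 = bivariate_pair_correlation(m, t1, ~t1)
            vals.append(np.mean(g12.values[1:]))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)

    def test_empty_type_rejected(self, rng):
        m = csr_map(rng, 0.01, WIN)
        with pytest.raises(ValueError, match="non-empty"):
            bivariate_pair_correlation(m, np.zeros(m.n, bool), np.ones(m.n, bool))


class TestMortalityStatistics:
    def test_exchangeable_labels_center_on_zero(self):
        """Coin-flip statuses on CSR: both contrasts average ~0 at every r."""
        r = np.random.default_rng(7)
        base = csr_map(r, 0.012, WIN)
        gc_sum = np.zeros(15)
        gd_sum = np.zeros(15)
        n_draws = 120
        for _ in range(n_draws):
            status = np.where(r.uniform(size=base.n) < 0.5, "killed", "alive")
            if len(set(status)) < 2:
                continue
            m = base.with_columns(status=status)
            gc, gd = mortality_difference_statistics(m)
            gc_sum += gc.values
            gd_sum += gd.values
        assert np.all(np.abs(gc_sum / n_draws) < 0.25)
        assert np.all(np.abs(gd_sum / n_draws) < 0.25)

    def test_clumped_dead_positive_cluster_statistic(self, rng):
        """Dead trees confined to one tight clump: g_cluster > 0 at short r,
        matching the brute-force pair-count oracle."""
        dead_pts = rng.normal(50, 2.0, (25, 2))
        alive_pts = rng.uniform(0, 100, (75, 2))
        coords = np.clip(np.vstack([dead_pts, alive_pts]), 0, 100)
        status = ["killed"] * 25 + ["alive"] * 75
        m = make_map(coords, WIN, status=status)
        gc, _ = mortality_difference_statistics(m)
        assert np.all(gc.values[:3] > 0)
        dead_idx = list(range(25))
        alive_idx = list(range(25, 100))
        ref = naive_bivariate_pcf(coords, dead_idx, dead_idx, WIN) - naive_bivariate_pcf(
            coords, alive_idx, dead_idx, WIN
        )
        np.testing.assert_allclose(gc.values, ref, rtol=1e-10)

    def test_density_dependent_kills_positive_densdep(self, rng):
        """Killing where local density is above median makes g_densdep > 0."""
        from scipy.spatial.distance import cdist

        base = csr_map(rng, 0.015, WIN)
        d = cdist(base.coords, base.coords)
        local = ((d <= 5) & (d > 0)).sum(axis=1)
        status = np.where(local > np.median(local), "killed", "alive")
        m = base.with_columns(status=status)
        _, gd = mortality_difference_statistics(m)
        assert np.nanmean(gd.values[:5]) > 0

    def test_all_one_status_rejected(self, rng):
        m = csr_map(rng, 0.01, WIN).with_columns(status="killed")
        with pytest.raises(ValueError, match="both statuses"):
            mortality_difference_statistics(m)


class TestMarkStatistics:
    def test_constant_marks_flat_kmark(self, rng):
        m = csr_map(rng, 0.01, WIN, dbh=30.0)
        k = r_mark_correlation(m)
        filled = k.values[~np.isnan(k.values)]
        assert filled == pytest.approx(30.0)

    def test_three_point_hand_oracle(self):
        """Collinear toy: ring values equal translation-weighted pair means."""
        win = PlotWindow(0, 50, 0, 50)
        coords = [(10.0, 25.0), (13.0, 25.0), (20.0, 25.0)]
        marks = [10.0, 20.0, 40.0]
        m = make_map(coords, win, dbh=marks)
        k = r_mark_correlation(m, r_max=15)
        g = mark_variogram(m, r_max=15, normalized=False)
        ref_k, ref_g = naive_mark_stats(coords, marks, win, r_max=15)
        np.testing.assert_allclose(k.values, ref_k, rtol=1e-12)
        np.testing.assert_allclose(g.values, ref_g, rtol=1e-12)
        # pair distances: 3 m (ring 2), 7 m (ring 6), 10 m (ring 9, on edge)
        assert not np.isnan(k.values[2]) and not np.isnan(k.values[6])
        assert np.isnan(k.values[3])

    def test_constant_marks_variogram(self, rng):
        m = csr_map(rng, 0.01, WIN, dbh=25.0)
        g = mark_variogram(m, normalized=False)
        filled = g.values[~np.isnan(g.values)]
        assert filled == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError, match="variance"):
            mark_variogram(m, normalized=True)

    def test_shuffled_marks_normalize_to_one(self, rng):
        """Marks independent of location: normalized variogram ~1 everywhere."""
        base = csr_map(rng, 0.012, WIN)
        dbh = rng.lognormal(3.5, 0.4, base.n)
        acc = np.zeros(15)
        n_shuffles = 100
        for _ in range(n_shuffles):
            m = base.with_columns(dbh=rng.permutation(dbh))
            acc += mark_variogram(m).values
        mean_curve = acc / n_shuffles
        # nearest rings hold very few pairs; test where the estimate is stable
        assert np.all(np.abs(mean_curve[2:] - 1.0) < 0.1)
        assert np.nanmean(mean_curve) == pytest.approx(1.0, abs=0.05)

    def test_mark_stats_match_naive_oracle(self, rng):
        m = csr_map(rng, 0.008, WIN)
        dbh = rng.uniform(10, 90, m.n)
        m = m.with_columns(dbh=dbh)
        k = r_mark_correlation(m)
        g = mark_variogram(m, normalized=False)
        ref_k, ref_g = naive_mark_stats(m.coords, dbh, WIN)
        np.testing.assert_allclose(k.values, ref_k, rtol=1e-10)
        np.testing.assert_allclose(g.values, ref_g, rtol=1e-10)


class TestSerialization:
    def test_correlation_function_to_csv(self, tmp_path, rng):
        m = csr_map(rng, 0.01, WIN)
        g = pair_correlation(m)
        path = tmp_path / "g.csv"
        g.to_csv(path)
        text = path.read_text()
        assert "kind=g_all" in text and "r,value" in text
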