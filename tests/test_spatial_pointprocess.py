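import math

import numpy as np
import pytest
from shapely.geometry import box

from immunoarch.core_io import PointPattern, UndefinedMetricError, WindowGrid, rectangle_window
from immunoarch.spatial_pointprocess import (
    MEAN_DIST_FACTOR,
    R95_FACTOR,
    ThomasFit,
    clark_evans_test,
    csr_envelope,
    default_r_grid,
    derived_cluster_stats,
    extract_windows,
    fit_thomas,
    pointwise_envelope,
    ripley_k,
    thomas_K_theoretical,
)
from immunoarch.synthetic_data import simulate_thomas


class TestExtractWindows:
    def test_overlapping_grid_on_square_millimeter(self):
        pp = PointPattern(np.array([[1.0, 1.0]]), rectangle_window(0, 0, 1000, 1000))
        wins = extract_windows(pp, WindowGrid(500, 500, 250, 250))
        assert len(wins) == 9  # 3 positions per axis

    def test_non_overlapping_tiling_partitions_points(self, rng):
        pts = rng.uniform(0, 1000, (200, 2))
        pp = PointPattern(pts, rectangle_window(0, 0, 1000, 1000))
        wins = extract_windows(pp, WindowGrid(500, 500, 500, 500))
        assert len(wins) == 4
        assert sum(sub.n for _, sub in wins) == 200

    def test_empty_pattern_gives_empty_windows(self):
        pp = PointPattern(np.empty((0, 2)), rectangle_window(0, 0, 1000, 1000))
        wins = extract_windows(pp, WindowGrid())
        assert all(sub.n == 0 for _, sub in wins)


class TestClarkEvans:
    def test_below_n_min_not_tested(self, window_500):
        pp = PointPattern(np.array([[10.0, 10.0], [20.0, 20.0]]), window_500)
        _, _, verdict = clark_evans_test(pp)
        assert verdict == "not_tested"

    def test_csr_index_near_one(self, rng, window_500):
        idx = []
        for _ in range(50):
            pts = np.column_stack([rng.uniform(0, 500, 120), rng.uniform(0, 500, 120)])
            ce, _, _ = clark_evans_test(PointPattern(pts, window_500))
            idx.append(ce)
        assert np.mean(idx) == pytest.approx(1.0, abs=0.1)

    def test_coincident_points_are_aggregated(self, window_500):
        pts = np.tile([[250.0, 250.0]], (30, 1))
        ce, p, verdict = clark_evans_test(PointPattern(pts, window_500))
        assert ce == 0.0 and verdict == "aggregated"

    def test_thomas_pattern_detected_as_aggregated(self, window_500):
        pp = simulate_thomas(window_500, kappa=40e-6, mu=15, sigma=25, rng=3)
        ce, p, verdict = clark_evans_test(pp)
        assert ce < 1.0
        assert verdict == "aggregated"

    def test_unknown_correction_rejected(self, csr_pattern):
        with pytest.raises(ValueError):
            clark_evans_test(csr_pattern, correction="toroidal")


class TestRipleyK:
    def test_no_pairs_below_first_distance(self, window_500):
        pp = PointPattern(np.array([[100.0, 100.0], [400.0, 100.0]]), window_500)
        est = ripley_k(pp, np.linspace(0, 125, 26))
        assert np.all(est.K_hat == 0)  # pair distance 300 > r_max 125

    def test_requires_two_points(self, window_500):
        with pytest.raises(UndefinedMetricError):
            ripley_k(PointPattern(np.array([[1.0, 1.0]]), window_500))

    def test_poisson_tracks_pi_r_squared(self, rng):
        win = rectangle_window(0, 0, 1000, 1000)
        rg = np.linspace(0, 250, 26)
        curves = []
        for _ in range(40):
            pts = rng.uniform(0, 1000, (200, 2))
            curves.append(ripley_k(PointPattern(pts, win), rg).K_hat)
        mean_K = np.mean(curves, axis=0)
        np.testing.assert_allclose(mean_K[5:], math.pi * rg[5:] ** 2, rtol=0.05)

    def test_regular_grid_shows_inhibition(self):
        g = np.arange(25.0, 500.0, 50.0)
        X, Y = np.meshgrid(g, g)
        pp = PointPattern(np.column_stack([X.ravel(), Y.ravel()]),
                          rectangle_window(0, 0, 500, 500))
        rg = np.array([0.0, 45.0])  # just below the 50 um spacing
        est = ripley_k(pp, rg)
        assert est.K_hat[1] == 0.0  # hard-core gap where CSR expects pi r^2 > 0

    def test_translation_invariance(self, rng, window_500):
        pts = rng.uniform(100, 400, (80, 2))
        rg = np.linspace(0, 100, 21)
        a = ripley_k(PointPattern(pts, window_500), rg).K_hat
        b = ripley_k(PointPattern(pts + 50.0, rectangle_window(50, 50, 550, 550)), rg).K_hat
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_l_transform(self, csr_pattern):
        est = ripley_k(csr_pattern)
        np.testing.assert_allclose(est.L_hat, np.sqrt(est.K_hat / math.pi))


class TestThomasTheory:
    def test_zero_at_origin(self):
        assert thomas_K_theoretical(0.0, 1e-5, 10.0) == 0.0

    def test_asymptote_beyond_cluster_scale(self):
        kappa, sigma = 1e-5, 10.0
        r = 500.0
        assert thomas_K_theoretical(r, kappa, sigma) == pytest.approx(
            math.pi * r**2 + 1 / kappa, rel=1e-9)

    def test_printed_example_value(self):
        # kappa = 50 mm^-2, sigma = 30 um at r = 50 um
        expected = math.pi * 2500 + 20000 * (1 - math.exp(-2500 / 3600))
        assert thomas_K_theoretical(50.0, 5e-5, 30.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_r_and_kappa(self):
        r = np.linspace(1, 200, 50)
        K = thomas_K_theoretical(r, 4e-5, 25.0)
        assert np.all(np.diff(K) > 0)
        assert thomas_K_theoretical(50.0, 4e-5, 25.0) > thomas_K_theoretical(50.0, 8e-5, 25.0)


class TestFitThomas:
    def test_recovers_single_tight_cluster(self, window_500):
        rng = np.random.default_rng(0)
        m = 40
        pts = rng.normal(250.0, 5.0, (m, 2))
        fit = fit_thomas(PointPattern(pts, window_500))
        assert fit.mu == pytest.approx(m, rel=0.35)
        assert fit.kappa == pytest.approx(1.0 / (500.0 * 500.0), rel=0.35)

    def test_intensity_constraint_exact(self, window_500):
        pp = simulate_thomas(window_500, kappa=40e-6, mu=15, sigma=25, rng=11)
        fit = fit_thomas(pp)
        assert fit.kappa * fit.mu == pytest.approx(pp.intensity, rel=1e-9)

    def test_poisson_misuse_flagged_unconverged(self, rng, window_500):
        flags = []
        for _ in range(10):
            pts = np.column_stack([rng.uniform(0, 500, 100), rng.uniform(0, 500, 100)])
            flags.append(fit_thomas(PointPattern(pts, window_500)).converged)
        assert sum(flags) <= 3  # CSR input should rarely look like a clustered fit

    def test_too_few_points_rejected(self, window_500):
        with pytest.raises(UndefinedMetricError):
            fit_thomas(PointPattern(np.array([[1.0, 1.0], [2.0, 2.0]]), window_500))

    def test_mincon_variant_runs(self, window_500):
        pp = simulate_thomas(window_500, kappa=40e-6, mu=15, sigma=25, rng=4)
        fit = fit_thomas(pp, method="mincon")
        assert fit.sigma > 0 and fit.kappa > 0


class TestDerivedStats:
    def test_rayleigh_closed_forms_at_unit_sigma(self):
        fit = ThomasFit(kappa=1e-5, mu=10, sigma=1.0, converged=True, objective=0.0)
        mean_dist, r95, area = derived_cluster_stats(fit)
        assert mean_dist == pytest.approx(math.sqrt(math.pi / 2), rel=1e-12)
        assert r95 == pytest.approx(math.sqrt(2 * math.log(20)), rel=1e-12)
        assert area == pytest.approx(math.pi * r95**2 / 1e6, rel=1e-12)

    def test_rayleigh_oracle_by_simulation(self, rng):
        # distance of isotropic Gaussian offsets is Rayleigh(sigma)
        r = np.hypot(*rng.normal(0, 1.0, (2, 200_000)))
        assert r.mean() == pytest.approx(MEAN_DIST_FACTOR, abs=2e-3)
        assert np.mean(r <= R95_FACTOR) == pytest.approx(0.95, abs=2e-3)

    def test_ratio_constant_for_every_fit(self, window_500):
        for seed in range(5):
            pp = simulate_thomas(window_500, kappa=40e-6, mu=15, sigma=25, rng=seed)
            fit = fit_thomas(pp)
            if not fit.converged:
                continue
            mean_dist, r95, _ = derived_cluster_stats(fit)
            assert r95 / mean_dist == pytest.approx(R95_FACTOR / MEAN_DIST_FACTOR, rel=1e-12)

    def test_unconverged_fit_has_no_stats(self):
        fit = ThomasFit(kappa=1e-5, mu=10, sigma=1.0, converged=False, objective=0.0)
        with pytest.raises(UndefinedMetricError):
            derived_cluster_stats(fit)


class TestEnvelopes:
    def test_min_max_convention_at_39_simulations(self, csr_pattern):
        rg = np.linspace(0, 125, 20)
        r, lo, hi = csr_envelope(csr_pattern, rg, n_sim=39, level=0.95, seed=0)
        assert lo.shape == hi.shape == rg.shape
        assert np.all(lo <= hi)

    def test_csr_curve_inside_csr_envelope(self, csr_pattern):
        rg = np.linspace(0, 125, 20)
        _, lo, hi = csr_envelope(csr_pattern, rg, n_sim=99, seed=1)
        # theoretical L(r) - r = 0 under CSR
        assert np.all(lo[1:] <= 0) and np.all(hi[1:] >= 0)

    def test_clustered_pattern_exits_upper_band(self, window_500):
        from immunoarch.spatial_pointprocess import ripley_k

        pp = simulate_thomas(window_500, kappa=40e-6, mu=15, sigma=25, rng=8)
        rg = np.linspace(0, 125, 20)
        _, lo, hi = csr_envelope(pp, rg, n_sim=99, seed=2)
        L_obs = ripley_k(pp, rg).L_hat - rg
        assert np.any(L_obs > hi)

    def test_global_rank_variant_is_wider(self, csr_pattern):
        rg = np.linspace(0, 125, 20)
        _, lo_p, hi_p = csr_envelope(csr_pattern, rg, n_sim=99, seed=3)
        _, lo_g, hi_g = csr_envelope(csr_pattern, rg, n_sim=99, seed=3, global_rank=True)
        assert np.all(hi_g >= hi_p - 1e-12)

    def test_pointwise_rank_arithmetic(self):
        curves = np.arange(40)[:, None] * np.ones((1, 3))
        lo, hi = pointwise_envelope(curves, level=0.95)
        np.testing.assert_allclose(lo, 0.0)
        np.testing.assert_allclose(hi, 39.0)
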