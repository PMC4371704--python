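import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegspike import (
    attractor_radius,
    canonical_signal,
    cao_functions,
    correlation_dimension,
    correlation_sum,
    divergence_curve,
    embed,
    largest_lyapunov,
    min_embedding_dimension,
    mutual_information,
    optimal_lag,
)
from eegspike.exceptions import (
    EstimationError,
    FitError,
    LagError,
    SegmentLengthError,
)
from eegspike.nonlinear_features import mutual_information_curve

from .oracles import (
    cao_brute,
    correlation_sum_brute,
    divergence_brute,
    embed_brute,
    mi_brute,
    takens_brute,
)


class TestMutualInformation:
    def test_perfect_dependence_is_one_bit(self):
        x = np.array([0.0, 0, 1, 1, 0, 0, 1, 1] * 2)[:8]
        # need >= 10 pairs: tile the pattern
        x = np.tile([0.0, 0, 1, 1], 5)
        assert mutual_information(x, lag=4, n_bins=2) == pytest.approx(1.0)

    def test_iid_noise_near_zero(self, rng):
        x = rng.uniform(size=4096)
        assert mutual_information(x, lag=10, n_bins=16) < 0.1

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_nonnegative(self, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        assert mutual_information(x, lag=3, n_bins=4) >= 0.0

    def test_matches_brute_force(self, rng):
        x = rng.standard_normal(150)
        for lag in (1, 5, 12):
            assert mutual_information(x, lag, 8) == pytest.approx(
                mi_brute(x, lag, 8), rel=1e-10
            )

    def test_excessive_lag_rejected(self, rng):
        with pytest.raises(LagError):
            mutual_information(rng.standard_normal(50), lag=50, n_bins=4)


class TestOptimalLag:
    def test_sine_mi_minimized_at_quarter_period(self):
        # the lag-MI of a sinusoid bottoms out where the two copies are in
        # quadrature; with coarse bins the curve is smooth enough for the
        # global minimum to sit at ~period/4
        x = np.sin(2 * np.pi * np.arange(4096) / 100)
        mi = mutual_information_curve(x, max_lag=40, n_bins=4)
        assert abs(int(np.argmin(mi)) + 1 - 25) <= 2

    def test_matches_rule_applied_to_brute_curve(self, rng):
        x = np.cumsum(rng.standard_normal(600))  # correlated -> structured MI
        max_lag = 30
        curve = [mi_brute(x, m, 8) for m in range(1, max_lag + 1)]
        expected = None
        for m in range(2, max_lag):
            if curve[m - 1] < curve[m - 2] and curve[m - 1] < curve[m]:
                expected = m
                break
        got = optimal_lag(x, max_lag=max_lag, n_bins=8)
        if expected is not None:
            assert got == expected

    def test_monotone_curve_falls_back_with_warning(self):
        # strongly low-pass signal: MI decays monotonically over short lags
        x = np.linspace(0, 1, 400) ** 2
        with pytest.warns(UserWarning, match="fallback"):
            optimal_lag(x, max_lag=10, n_bins=4)


class TestEmbed:
    def test_small_example(self):
        pts = embed(np.array([1.0, 2, 3, 4, 5]), lag=2, dim=2)
        np.testing.assert_array_equal(pts, [[1, 3], [2, 4], [3, 5]])

    def test_dim_one_is_identity(self, rng):
        x = rng.standard_normal(20)
        np.testing.assert_array_equal(embed(x, lag=3, dim=1).ravel(), x)

    @given(
        n=st.integers(20, 100), lag=st.integers(1, 5), dim=st.integers(1, 4)
    )
    @settings(max_examples=30, deadline=None)
    def test_point_count_formula(self, n, lag, dim):
        x = np.arange(float(n))
        pts = embed(x, lag, dim)
        assert pts.shape == (n - lag * (dim - 1), dim)
        np.testing.assert_array_equal(pts, embed_brute(x, lag, dim))

    def test_insufficient_length(self):
        with pytest.raises(SegmentLengthError):
            embed(np.arange(5.0), lag=3, dim=3)


class TestCao:
    def test_matches_brute_force_small_fixture(self, rng):
        x = rng.standard_normal(30)
        e, e_star = cao_functions(x, lag=1, d_max=4)
        e_b, e_star_b = cao_brute(x, lag=1, d_max=4)
        np.testing.assert_allclose(e, e_b, rtol=1e-10)
        np.testing.assert_allclose(e_star, e_star_b, rtol=1e-10)

    def test_henon_saturates_at_two(self):
        x = canonical_signal("henon_map", n=2000).samples
        e, _ = cao_functions(x, lag=1, d_max=5, seed=0)
        assert min_embedding_dimension(e, threshold=0.05) == 2

    def test_noise_estar_ratio_stays_near_one(self, rng):
        x = rng.standard_normal(2000)
        _, e_star = cao_functions(x, lag=1, d_max=5, seed=0)
        ratios = e_star[1:] / e_star[:-1]
        assert np.all(np.abs(ratios - 1) < 0.1)

    def test_truncates_with_warning_when_short(self):
        with pytest.warns(UserWarning, match="truncating"):
            e, _ = cao_functions(np.sin(np.arange(30.0)), lag=5, d_max=8)
        assert len(e) < 8


class TestMinEmbeddingDimension:
    def test_direct_rule(self):
        assert min_embedding_dimension(np.array([0.5, 0.9, 0.91, 0.915])) == 2

    def test_constant_sequence_gives_one(self):
        assert min_embedding_dimension(np.array([0.7, 0.7, 0.7])) == 1

    def test_never_saturating_returns_dmax_with_warning(self):
        with pytest.warns(UserWarning, match="saturat"):
            d = min_embedding_dimension(np.array([1.0, 2.0, 4.0, 8.0]), threshold=0.0)
        assert d == 4


class TestAttractorRadius:
    def test_unit_square_corners(self):
        pts = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        assert attractor_radius(pts, fraction=0.05) == pytest.approx(0.05 * np.sqrt(2))

    def test_exact_when_no_subsampling(self, rng):
        pts = rng.standard_normal((50, 3))
        eps = attractor_radius(pts, fraction=1.0, sample_size=100)
        brute = max(
            np.linalg.norm(pts[i] - pts[j])
            for i in range(50)
            for j in range(i + 1, 50)
        )
        assert eps == pytest.approx(brute, rel=1e-12)

    def test_subsample_close_to_exhaustive(self, rng):
        pts = rng.standard_normal((3000, 2))
        sub = attractor_radius(pts, fraction=1.0, sample_size=800, seed=0)
        full = attractor_radius(pts, fraction=1.0, sample_size=3000)
        assert sub == pytest.approx(full, rel=0.05)

    def test_single_point_rejected(self):
        with pytest.raises(EstimationError):
            attractor_radius(np.zeros((1, 2)))


class TestCorrelationDimension:
    def test_interval_cloud_has_dimension_one(self, rng):
        u = np.sort(rng.uniform(size=2000))
        pts = np.column_stack([u, np.zeros_like(u)])
        eps = attractor_radius(pts, fraction=0.05, sample_size=2000)
        d = correlation_dimension(pts, eps, max_points=2000)
        assert d == pytest.approx(1.0, abs=0.15)

    def test_square_cloud_has_dimension_two(self, rng):
        pts = rng.uniform(size=(2000, 2))
        eps = attractor_radius(pts, fraction=0.05, sample_size=2000)
        d = correlation_dimension(pts, eps, max_points=2000)
        assert d == pytest.approx(2.0, abs=0.2)

    def test_matches_brute_force_takens(self, rng):
        pts = rng.uniform(size=(120, 2))
        eps = 0.3
        assert correlation_dimension(pts, eps, max_points=200) == pytest.approx(
            takens_brute(pts, eps), rel=1e-10
        )

    def test_correlation_sum_matches_brute_force(self, rng):
        pts = rng.uniform(size=(100, 2))
        assert correlation_sum(pts, 0.25) == pytest.approx(
            correlation_sum_brute(pts, 0.25), rel=1e-12
        )

    def test_repeated_point_rejected(self):
        pts = np.zeros((10, 2))
        with pytest.raises(EstimationError):
            correlation_dimension(pts, eps=0.5)

    def test_does_not_exceed_ambient_dimension(self, rng):
        for dim in (1, 2, 3):
            pts = rng.uniform(size=(1500, dim))
            eps = attractor_radius(pts, fraction=0.05, sample_size=1500)
            d = correlation_dimension(pts, eps, max_points=1500)
            assert d <= dim + 0.3

    def test_affine_rescaling_invariance(self, rng):
        # radius scales with the attractor, so the estimate is scale-free
        pts = rng.uniform(size=(800, 2))
        for scale in (0.01, 1.0, 250.0):
            q = scale * pts + 3.0
            eps = attractor_radius(q, fraction=0.05, sample_size=800)
            d = correlation_dimension(q, eps, max_points=800)
            eps0 = attractor_radius(pts, fraction=0.05, sample_size=800)
            d0 = correlation_dimension(pts, eps0, max_points=800)
            assert d == pytest.approx(d0, rel=1e-9)


class TestDivergenceCurve:
    def test_sato_matches_brute_force(self, rng):
        pts = embed(np.cumsum(rng.standard_normal(110)), lag=1, dim=3)
        got = divergence_curve(pts, k=6, mode="sato", theiler=3, max_points=200)
        exp = divergence_brute(pts, k=6, mode="sato", theiler=3)
        np.testing.assert_allclose(got, exp, rtol=1e-10)

    def test_wolf_matches_brute_force(self, rng):
        pts = embed(np.cumsum(rng.standard_normal(110)), lag=1, dim=3)
        got = divergence_curve(pts, k=6, mode="wolf", theiler=3, max_points=200)
        exp = divergence_brute(pts, k=6, mode="wolf", theiler=3)
        np.testing.assert_allclose(got, exp, rtol=1e-10)

    def test_duplicated_trajectory_gives_zero_curve(self, rng):
        # three stacked copies: every reference has an exact duplicate among
        # the neighbor candidates, so initial and evolved distances are all 0
        traj = embed(np.sin(np.arange(40.0) * 0.3), lag=1, dim=2)
        pts = np.vstack([traj, traj, traj])
        curve = divergence_curve(pts, k=4, mode="sato", theiler=0, max_points=200)
        np.testing.assert_array_equal(curve, np.zeros(4))

    def test_wolf_and_sato_differ_as_mean_orders(self, rng):
        # log2 of the mean ratio vs mean of log2 ratios: both computed
        # independently by brute force, equal only in degenerate cases
        pts = rng.uniform(size=(10, 2))
        wolf = divergence_brute(pts, k=2, mode="wolf", theiler=0)
        sato = divergence_brute(pts, k=2, mode="sato", theiler=0)
        got_w = divergence_curve(pts, k=2, mode="wolf", theiler=0)
        got_s = divergence_curve(pts, k=2, mode="sato", theiler=0)
        np.testing.assert_allclose(got_w, wolf, rtol=1e-10)
        np.testing.assert_allclose(got_s, sato, rtol=1e-10)
        # Jensen: mean of logs <= log of mean
        assert np.all(np.asarray(sato) <= np.log2(np.asarray(wolf)) + 1e-12)

    def test_horizon_error(self, rng):
        with pytest.raises(EstimationError):
            divergence_curve(rng.uniform(size=(5, 2)), k=5)


class TestLargestLyapunov:
    def test_exact_linear_curve(self):
        ts = 0.5
        curve = 3.0 * np.arange(1, 13) * ts  # p_k = 3 * k * Ts (bits)
        lam = largest_lyapunov(curve, ts=ts)
        assert lam == pytest.approx(3.0 * np.log(2), rel=1e-12)

    def test_logistic_map_ln2(self):
        x = canonical_signal("logistic_map", n=4000).samples
        pts = embed(x, lag=1, dim=2)
        curve = divergence_curve(pts, k=10, mode="sato", theiler=2, max_points=1000, seed=0)
        lam = largest_lyapunov(curve, ts=1.0)
        assert lam == pytest.approx(np.log(2), rel=0.15)

    def test_pure_sine_near_zero(self):
        x = np.sin(2 * np.pi * np.arange(4096) / 100)
        pts = embed(x, lag=25, dim=2)
        curve = divergence_curve(pts, k=10, mode="sato", theiler=50, max_points=1000, seed=0)
        lam = largest_lyapunov(curve, ts=1.0)
        assert abs(lam) < 0.05

    def test_too_few_fit_points(self):
        with pytest.raises(FitError):
            largest_lyapunov(np.arange(4.0), fit_lo=0.9, fit_hi=0.95)


class TestReproducibility:
    def test_seeded_runs_bit_identical(self, rng):
        x = rng.standard_normal(3000)
        pts = embed(x, lag=2, dim=4)
        a = divergence_curve(pts, k=8, theiler=8, max_points=500, seed=42)
        b = divergence_curve(pts, k=8, theiler=8, max_points=500, seed=42)
        np.testing.assert_array_equal(a, b)
        ca, _ = cao_functions(x, lag=2, d_max=4, max_points=500, seed=7)
        cb, _ = cao_functions(x, lag=2, d_max=4, max_points=500, seed=7)
        np.testing.assert_array_equal(ca, cb)
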