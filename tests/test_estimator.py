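"""The TWO-NN pipeline: mu ratios, cumulate, origin fit, full estimator."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from twonn import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidParameterError,
    NeighborDistances,
    compute_mu,
    empirical_cumulate,
    estimate_id,
    estimate_id_from_mu,
    fit_through_origin,
    gen_cauchy,
    gen_hypercube,
    quantile_mu,
    two_nearest,
)
from conftest import pairwise_euclidean


def _nd(r1, r2):
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    idx = np.zeros(len(r1), dtype=int)
    return NeighborDistances(r1=r1, r2=r2, index_1=idx, index_2=idx)


class TestComputeMu:
    def test_simple_ratios(self):
        ms = compute_mu(_nd([1.0, 2.0], [3.0, 2.0]))
        np.testing.assert_allclose(ms.mu, [3.0, 1.0])

    def test_zero_r1_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_mu(_nd([0.0, 1.0], [1.0, 2.0]))

    def test_uniform_2d_matches_pareto_law(self):
        """mu from a homogeneous 2-D sample follows F(mu) = 1 - mu^-2."""
        X = gen_hypercube(10_000, 2, seed=31)
        ms = compute_mu(two_nearest(X, box=[1.0, 1.0]))
        res = stats.kstest(ms.mu, lambda m: 1.0 - np.asarray(m, float) ** -2.0)
        assert res.pvalue > 1e-3


class TestEmpiricalCumulate:
    def test_three_values(self):
        mu, F = empirical_cumulate(np.array([2.0, 4.0, 8.0]))
        np.testing.assert_allclose(F, [1 / 3, 2 / 3, 1.0])
        np.testing.assert_allclose(mu, [2.0, 4.0, 8.0])

    def test_ties_get_consecutive_ranks(self):
        mu, F = empirical_cumulate(np.array([5.0, 5.0, 5.0, 5.0]))
        np.testing.assert_allclose(F, [0.25, 0.5, 0.75, 1.0])

    @given(
        st.lists(st.floats(min_value=1.0, max_value=1e6), min_size=2, max_size=200)
    )
    @settings(deadline=None, derandomize=True)
    def test_nondecreasing_and_ends_at_one(self, values):
        mu, F = empirical_cumulate(np.array(values))
        assert np.all(np.diff(mu) >= 0)
        assert np.all(np.diff(F) > 0)
        assert F[-1] == 1.0

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            empirical_cumulate(np.array([1.5]))


class TestFitThroughOrigin:
    def test_exact_line(self):
        assert fit_through_origin([1.0, 2.0], [2.0, 4.0]) == pytest.approx(2.0)

    def test_closed_form(self):
        # sum(xy)/sum(x^2) = 9/5
        assert fit_through_origin([1.0, 2.0], [1.0, 4.0]) == pytest.approx(1.8)

    def test_matches_least_squares_solver(self):
        rng = np.random.default_rng(32)
        for _ in range(5):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            direct = fit_through_origin(x, y)
            (slope,), _, _, _ = np.linalg.lstsq(x[:, None], y)
            assert direct == pytest.approx(slope, abs=1e-10)

    def test_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_through_origin([0.0, 0.0], [1.0, 2.0])


class TestEstimateId:
    def test_quantile_injection_recovers_d(self):
        """Exact Pareto quantiles at d=5 drive the fitted slope to 5."""
        for M, tol in ((1_000, 0.05), (100_000, 0.005)):
            p = (np.arange(1, M + 1) - 0.5) / M
            mu = quantile_mu(p, 5.0)
            est = estimate_id_from_mu(mu, discard_fraction=0.10)
            assert est.d_hat == pytest.approx(5.0, rel=tol)

    def test_scale_invariance_exact(self):
        X = gen_hypercube(500, 3, seed=33)
        base = estimate_id(X)
        scaled = estimate_id(2.0 * X)  # power of two: distances scale exactly
        assert scaled.d_hat == base.d_hat

    def test_scale_invariance_distance_matrix(self):
        X = np.random.default_rng(34).normal(size=(200, 4))
        D = pairwise_euclidean(X)
        base = estimate_id(D, metric="precomputed")
        scaled = estimate_id(2.0 * D, metric="precomputed")
        assert scaled.d_hat == base.d_hat

    def test_matrix_route_equals_coordinate_route(self):
        X = np.random.default_rng(35).normal(size=(300, 3))
        a = estimate_id(X)
        b = estimate_id(pairwise_euclidean(X), metric="precomputed")
        assert a.d_hat == pytest.approx(b.d_hat, rel=1e-12)
        assert (a.n_total, a.n_used) == (b.n_total, b.n_used)

    def test_n_used_accounting(self):
        X = gen_hypercube(1000, 2, seed=36)
        est = estimate_id(X, discard_fraction=0.10)
        assert est.n_total == 1000
        assert est.n_used == 900
        assert len(est.fit_x) == 900
        assert np.all(np.diff(est.fit_x) >= 0)

    def test_discard_zero_warns_and_drops_top_point(self):
        X = gen_hypercube(200, 2, seed=37)
        with pytest.warns(UserWarning, match="maximal-mu"):
            est = estimate_id(X, discard_fraction=0.0)
        assert est.n_used == 200
        assert len(est.fit_x) == 199
        assert np.all(np.isfinite(est.fit_y))

    def test_discard_direction_heavy_tail_vs_uniform(self):
        """Discarding the tail barely moves the hypercube estimate but raises
        the Cauchy estimate (the heavy tail drags the full fit down)."""
        up_cube, up_cauchy = [], []
        for seed in range(5):
            cube = gen_hypercube(2500, 14, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = estimate_id(cube, discard_fraction=0.0, box=[1.0] * 14).d_hat
            disc = estimate_id(cube, discard_fraction=0.10, box=[1.0] * 14).d_hat
            up_cube.append(abs(disc - full) / full)

            cauchy = gen_cauchy(2500, 20, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full_c = estimate_id(cauchy, discard_fraction=0.0).d_hat
            disc_c = estimate_id(cauchy, discard_fraction=0.10).d_hat
            up_cauchy.append(disc_c - full_c)
        assert np.mean(up_cube) < 0.02
        assert np.mean(up_cauchy) > 0

    def test_parameter_recovery_hypercube(self):
        """Uniform hypercube with periodic metric recovers d within 5%."""
        for d in (2, 5):
            vals = [
                estimate_id(gen_hypercube(5000, d, seed=s), box=[1.0] * d).d_hat
                for s in range(3)
            ]
            assert np.mean(vals) == pytest.approx(d, rel=0.05)

    def test_error_paths(self):
        X = gen_hypercube(10, 2, seed=38)
        with pytest.raises(InvalidParameterError):
            estimate_id(X, discard_fraction=1.0)
        with pytest.raises(InsufficientDataError):
            estimate_id(X, discard_fraction=0.9)
        with pytest.raises(InvalidParameterError):
            estimate_id(X, metric="cosine")
        with pytest.raises(InvalidParameterError):
            estimate_id(pairwise_euclidean(X), metric="precomputed", box=[1.0])
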