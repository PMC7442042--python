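"""Posterior weights, mean, covariance, sampler and bias diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bmbands.design import eigen_system, from_coefficients, make_design, to_coefficients
from bmbands.posterior import (
    decompose,
    discrete_bias,
    posterior_cov,
    posterior_design_mean,
    posterior_mean,
    posterior_state,
    sample_centered_design,
    sample_posterior_paths,
    shrinkage_factors,
    weights,
    weights_dense,
)


class TestWeights:
    def test_boundary_identity(self):
        grid = make_design(100)
        w = weights(0.35, 2.0, grid)
        lhs = 1.0 - w.weights.sum()
        rhs = (grid.n_plus / 2.0) * w.weights[0]
        assert abs(lhs - rhs) < 1e-10 * abs(rhs)

    @pytest.mark.parametrize("x,c", [(0.05, 0.3), (0.4, 1.0), (0.77, 9.0), (1.0, 2.0),
                                     (0.01, 5.0), (0.96, 0.1)])
    def test_matches_dense_solve(self, x, c):
        grid = make_design(12)
        a = weights(x, c, grid).weights
        np.testing.assert_allclose(a, weights_dense(x, c, grid), atol=1e-9)

    def test_noiseless_limit_is_interpolation(self):
        # huge c: observing Y pins f at the design points, weights -> e_k
        grid = make_design(30)
        k = 11
        a = weights(grid.points[k], 1e8, grid).weights
        unit = np.zeros(30)
        unit[k] = 1.0
        np.testing.assert_allclose(a, unit, atol=1e-5)

    def test_beyond_last_design_point(self):
        grid = make_design(40)
        a_end = weights(grid.points[-1], 1.5, grid).weights
        a_past = weights(0.999, 1.5, grid).weights
        np.testing.assert_allclose(a_past, a_end, atol=1e-14)

    def test_nonnegative_and_lambda_plus(self):
        grid = make_design(60)
        w = weights(0.5, 3.0, grid)
        assert w.weights.min() >= -1e-13
        r = 3.0 / grid.n_plus
        assert w.lambda_plus == pytest.approx(1 + np.sqrt(r) * np.sqrt(1 + r / 4) + r / 2)

    @pytest.mark.parametrize("x,c", [(0.0, 1.0), (-0.2, 1.0), (1.1, 1.0), (0.5, 0.0), (0.5, -2.0)])
    def test_invalid_arguments(self, x, c):
        with pytest.raises(ValueError):
            weights(x, c, make_design(10))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(5, 60), logc=st.floats(-2, 2), x=st.floats(0.01, 1.0))
    def test_dense_oracle_property(self, n, logc, x):
        grid = make_design(n)
        c = 10.0**logc
        np.testing.assert_allclose(
            weights(x, c, grid).weights, weights_dense(x, c, grid), atol=1e-8)

    def test_exponential_decay_envelope(self):
        # frozen envelope constant 6 with a small absolute floor for the
        # float64 tail of the tridiagonal solve
        for n, c, x in [(200, 1.0, 0.5), (200, 20.0, 0.3), (1000, 5.0, 0.8)]:
            grid = make_design(n)
            a = weights(x, c, grid).weights
            env = 6.0 * np.sqrt(c / n) * np.exp(-np.abs(x - grid.points) * np.sqrt(c * n) / 2)
            assert np.all(a <= env + 1e-12)

    def test_sum_rule_envelope(self):
        for n in (100, 500):
            grid = make_design(n)
            for c in (0.5, 5.0):
                for x in (0.2, 0.5, 0.9):
                    s = weights(x, c, grid).weights.sum()
                    assert abs(s - 1.0) <= 2.0 * np.exp(-x * np.sqrt(c * n) / 2) + 1e-11


class TestPosteriorMean:
    def test_zero_data_gives_zero(self):
        xs = np.linspace(0.05, 1.0, 13)
        np.testing.assert_array_equal(posterior_mean(np.zeros(25), 1.0, xs), np.zeros(13))

    def test_spectral_matches_weights_at_design_points(self, rng):
        grid = make_design(200)
        y = rng.standard_normal(200)
        spectral = posterior_mean(y, 0.8, grid.points)
        direct = np.array([weights(x, 0.8, grid).weights @ y for x in grid.points])
        np.testing.assert_allclose(spectral, direct, atol=1e-8)

    def test_linear_interpolation_between_design_points(self, rng):
        grid = make_design(80)
        y = rng.standard_normal(80)
        k = 30
        mid = 0.5 * (grid.points[k] + grid.points[k + 1])
        at_mid = posterior_mean(y, 2.0, [mid])[0]
        flank = posterior_mean(y, 2.0, grid.points[[k, k + 1]])
        assert abs(at_mid - flank.mean()) < 1e-9
        # and the weight-based evaluation agrees between design points
        direct = weights(mid, 2.0, grid).weights @ y
        assert abs(at_mid - direct) < 1e-9

    def test_tridiagonal_design_mean_matches_spectral(self, rng):
        y = rng.standard_normal(300)
        np.testing.assert_allclose(
            posterior_design_mean(y, 1.7),
            posterior_state(y, 1.7).design_mean, atol=1e-10)

    def test_linearity_in_data(self, rng):
        y1, y2 = rng.standard_normal((2, 40))
        xs = np.linspace(0.1, 0.9, 7)
        np.testing.assert_allclose(
            posterior_mean(y1 + 2 * y2, 1.0, xs),
            posterior_mean(y1, 1.0, xs) + 2 * posterior_mean(y2, 1.0, xs), atol=1e-12)


class TestPosteriorCovariance:
    def test_spectral_diagonalisation(self, basis50, rng):
        grid = basis50.grid
        cov = np.array([[posterior_cov(x, y, 1.0, grid) for y in grid.points]
                        for x in grid.points])
        e_mat = basis50.basis_block(1, 50)
        spec = e_mat @ cov @ e_mat.T
        np.testing.assert_allclose(np.diag(spec), shrinkage_factors(1.0, basis50), atol=1e-8)
        assert np.abs(spec - np.diag(np.diag(spec))).max() < 1e-8

    def test_symmetry_and_positive_variance(self):
        grid = make_design(30)
        assert posterior_cov(0.3, 0.7, 2.0, grid) == pytest.approx(
            posterior_cov(0.7, 0.3, 2.0, grid), abs=1e-14)
        for x in (0.05, 0.5, 0.98):
            assert posterior_cov(x, x, 2.0, grid) > 0

    def test_grid_covariance_psd(self):
        grid = make_design(30)
        xs = np.linspace(0.08, 0.95, 12)
        cov = np.array([[posterior_cov(x, y, 0.6, grid) for y in xs] for x in xs])
        assert np.linalg.eigvalsh(cov).min() > -1e-8

    def test_tau_identity(self, rng):
        grid = make_design(40)
        state = posterior_state(rng.standard_normal(40), 1.2)
        ax = weights(0.3, 1.2, grid).weights
        ay = weights(0.6, 1.2, grid).weights
        assert state.tau(0.3, 0.6) == pytest.approx(float(ax @ ay), abs=1e-10)


class TestSampler:
    def test_deterministic_under_seed(self, rng):
        y = rng.standard_normal(30)
        g1, p1 = sample_posterior_paths(y, 1.0, 4, subgrid_factor=3, seed=7)
        g2, p2 = sample_posterior_paths(y, 1.0, 4, subgrid_factor=3, seed=7)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(g1, g2)
        assert np.all(np.diff(g1) > 0) and g1[0] == 0.0 and g1[-1] == 1.0

    def test_spectral_variance_at_design_points(self):
        n, c, draws = 30, 0.9, 20000
        basis = eigen_system(n)
        g, paths = sample_posterior_paths(np.zeros(n), c, draws, subgrid_factor=1,
                                          seed=3, centered=True)
        didx = np.searchsorted(g, basis.grid.points)
        coef = to_coefficients(paths[:, didx], basis)
        emp = coef.var(axis=0)
        anal = shrinkage_factors(c, basis)
        se = anal * np.sqrt(2.0 / draws)
        assert np.all(np.abs(emp - anal) < 4 * se)

    def test_bridge_midpoint_variance(self):
        n, c, draws = 20, 1.4, 20000
        grid = make_design(n)
        g, paths = sample_posterior_paths(np.zeros(n), c, draws, subgrid_factor=1,
                                          seed=5, centered=True)
        h = 1.0 / grid.n_plus
        k = 8
        mid_idx = np.searchsorted(g, grid.points[k] + h / 2)
        didx = np.searchsorted(g, grid.points[[k, k + 1]])
        resid = paths[:, mid_idx] - paths[:, didx].mean(axis=1)
        target = c * h / 4.0
        assert abs(resid.var() - target) < 4 * target * np.sqrt(2.0 / draws)

    def test_banded_sampler_matches_posterior_law(self):
        # sample via the tridiagonal precision; compare spectral variances
        n, c, draws = 50, 1.3, 30000
        basis = eigen_system(n)
        x = sample_centered_design(n, c, draws, np.random.default_rng(11))
        emp = to_coefficients(x, basis).var(axis=0)
        anal = shrinkage_factors(c, basis)
        assert np.all(np.abs(emp - anal) < 4.5 * anal * np.sqrt(2.0 / draws))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            sample_posterior_paths(np.zeros(10), 1.0, 0)
        with pytest.raises(ValueError):
            sample_posterior_paths(np.zeros(10), 1.0, 2, subgrid_factor=0)


class TestBiasDecomposition:
    def test_zero_function_has_zero_bias(self, rng):
        y = rng.standard_normal(25)
        dec = decompose(lambda xs: np.zeros_like(xs), y, 1.0, np.linspace(0.1, 0.9, 9))
        np.testing.assert_allclose(dec.bias, 0.0, atol=1e-14)

    def test_decomposition_identity(self, basis50, rng):
        grid = basis50.grid
        f_coef = rng.standard_normal(50)
        f_vals = from_coefficients(f_coef, basis50)
        f = lambda xs: np.interp(xs, np.concatenate(([0.0], grid.points)),
                                 np.concatenate(([0.0], f_vals)))
        y = f_vals + rng.standard_normal(50)
        dec = decompose(f, y, 1.3, grid.points)
        fhat = posterior_mean(y, 1.3, grid.points)
        np.testing.assert_allclose(dec.centered + dec.bias, fhat - f_vals, atol=1e-12)

    def test_kink_bias_rate(self):
        # sup-norm smoothing bias of the Hölder-1/4 kink decays like
        # (cn)^{-alpha/2}: slope -1/8 in log(cn)
        from bmbands.functions import kink_function

        n = 2000
        kink = kink_function(0.75, 0.25)
        y = kink.design_values(n)  # noiseless: T_n = 0
        xs = np.linspace(0.1, 0.9, 2001)  # includes the kink at 0.75
        cs = [1.0, 10.0, 100.0, 1000.0]
        sups = [np.abs(decompose(kink, y, c, xs).bias).max() for c in cs]
        slope = np.polyfit(np.log(np.asarray(cs) * n), np.log(sups), 1)[0]
        assert slope == pytest.approx(-0.125, abs=0.05)


class TestDiscreteBias:
    def test_matches_weight_based_bias(self, rng):
        n = 100
        basis = eigen_system(n)
        grid = basis.grid
        f_coef = rng.standard_normal(n)
        f_vals = from_coefficients(f_coef, basis)
        spectral = discrete_bias(f_coef, 1.0, basis)
        direct = np.array([weights(x, 1.0, grid).weights @ f_vals for x in grid.points]) - f_vals
        np.testing.assert_allclose(spectral, direct, atol=1e-8)

    def test_vanishes_for_huge_scale(self, rng):
        f_coef = rng.standard_normal(80)
        bias = discrete_bias(f_coef, 1e10)
        assert np.abs(bias).max() < 1e-4 * np.linalg.norm(f_coef)

    def test_single_coefficient_pattern(self, basis50):
        f_coef = np.zeros(50)
        f_coef[9] = 1.0
        expected = -basis50.basis_vector(10) / (1.0 + 2.0 * basis50.eigenvalues[9])
        np.testing.assert_allclose(discrete_bias(f_coef, 2.0, basis50), expected, atol=1e-10)
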