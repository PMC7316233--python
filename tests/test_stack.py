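"""Meta-model tests: exact-Gaussian oracle equivalence, weight recovery,
prediction surfaces and predictive densities."""

import numpy as np
import pytest
from scipy.optimize import nnls
from scipy.stats import kstest

from resistmap import gmrf
from resistmap.stack import (
    PredictionSurface,
    StackPosterior,
    StackPriors,
    fit_stack,
    predict_stack,
    predictive_density,
)
from resistmap.transforms import inverse_transform

from conftest import make_grid


def _toy_fit_inputs(seed=1, n=20, nr=5, nc=5, nt=2, p=2):
    rng = np.random.default_rng(seed)
    grid = make_grid(nr, nc, nt)
    node = rng.integers(0, grid.n_pixels * nt, n)
    m = rng.standard_normal((n, p))
    params = dict(field_sd=0.8, field_range=0.7, temporal_rho=0.5, sigma=0.3)
    f = gmrf.sample_field(nr, nc, nt, params["field_range"] / grid.cell_size,
                          params["field_sd"], params["temporal_rho"], rng)[0].ravel()
    w_true = np.array([0.7, 0.4])[:p]
    y = m @ w_true + f[node] + params["sigma"] * rng.standard_normal(n)
    return y, m, node, grid, params


def _dense_oracle(y, m, node, grid, params, tau):
    """Closed-form Gaussian conditioning with dense linear algebra."""
    q, _ = gmrf.space_time_precision(
        grid.n_rows, grid.n_cols, grid.n_years,
        params["field_range"] / grid.cell_size, params["field_sd"], params["temporal_rho"],
    )
    cov_f = np.linalg.inv(q.toarray())
    n = len(y)
    sigma_y = cov_f[np.ix_(node, node)] + params["sigma"] ** 2 * np.eye(n)
    si = np.linalg.inv(sigma_y)
    p = m.shape[1]
    w_mean = np.linalg.solve(m.T @ si @ m + np.eye(p) / tau**2, m.T @ si @ y)
    # field posterior mean: cov(f, y) Sigma^-1 (y - M w), accounting for w uncertainty
    # full joint: z = [w, f]; use precision form for exactness
    a = np.zeros((n, q.shape[0]))
    a[np.arange(n), node] = 1.0
    b = np.hstack([m, a])
    prior_prec = np.block([
        [np.eye(p) / tau**2, np.zeros((p, q.shape[0]))],
        [np.zeros((q.shape[0], p)), q.toarray()],
    ])
    post_prec = prior_prec + b.T @ b / params["sigma"] ** 2
    mean = np.linalg.solve(post_prec, b.T @ y / params["sigma"] ** 2)
    return mean[:p], mean[p:]


class TestOracleEquivalence:
    def test_posterior_mean_matches_dense_conditioning(self):
        y, m, node, grid, params = _toy_fit_inputs()
        post = fit_stack(y, m, node, grid, seed=0, n_draws=50,
                         fixed_params=params, constrain_weights=False)
        w_oracle, f_oracle = _dense_oracle(y, m, node, grid, params, StackPriors().weight_sd)
        assert np.allclose(post.cond_mean_weights, w_oracle, rtol=1e-6)
        assert np.allclose(post.cond_mean_field, f_oracle, rtol=1e-6, atol=1e-9)

    def test_draw_moments_match_conditional(self):
        y, m, node, grid, params = _toy_fit_inputs()
        post = fit_stack(y, m, node, grid, seed=0, n_draws=4000,
                         fixed_params=params, constrain_weights=False)
        assert np.allclose(post.weights.mean(axis=0), post.cond_mean_weights, atol=0.02)


class TestWeightRecovery:
    def test_truth_column_dominates(self):
        rng = np.random.default_rng(2)
        grid = make_grid(6, 6, 2)
        n = 120
        node = rng.integers(0, grid.n_pixels * 2, n)
        truth = rng.standard_normal(n)
        m = np.column_stack([truth + 0.01 * rng.standard_normal(n), rng.standard_normal(n)])
        y = truth
        params = dict(field_sd=1e-3, field_range=0.5, temporal_rho=0.1, sigma=0.1)
        post = fit_stack(y, m, node, grid, seed=0, n_draws=200, fixed_params=params)
        w = post.weight_mean()
        assert w[0] > 0.9
        assert w[1] < 0.1
        # constrained GLS oracle on the same data
        w_nnls, _ = nnls(m, y)
        assert np.allclose(w, w_nnls, atol=0.05)

    def test_zero_labels_give_zero_predictions(self):
        y, m, node, grid, params = _toy_fit_inputs()
        y = np.zeros_like(y)
        post = fit_stack(y, m, node, grid, seed=0, n_draws=300, fixed_params=params,
                         constrain_weights=False)
        mu = post.weights @ m.T + post.field[:, node]
        assert np.abs(mu.mean(axis=0)).max() < 0.1
        assert np.abs(post.cond_mean_weights).max() < 1e-6  # exact mean is 0

    def test_rank_deficient_design_warns(self):
        y, m, node, grid, params = _toy_fit_inputs()
        m2 = np.column_stack([m[:, 0], m[:, 0]])
        with pytest.warns(UserWarning, match="rank deficient"):
            fit_stack(y, m2, node, grid, seed=0, n_draws=20, fixed_params=params)

    def test_single_model_rejected(self):
        y, m, node, grid, params = _toy_fit_inputs()
        with pytest.raises(ValueError):
            fit_stack(y, m[:, :1], node, grid, fixed_params=params)

    def test_constrained_draws_nonnegative(self):
        y, m, node, grid, params = _toy_fit_inputs()
        post = fit_stack(y, m, node, grid, seed=0, n_draws=100, fixed_params=params)
        assert np.all(post.weights >= 0)


def _degenerate_posterior(grid, value, p=2):
    n_nodes = grid.n_pixels * grid.n_years
    return StackPosterior(
        weights=np.tile([0.5, 0.5], (120, 1)),
        field=np.full((120, n_nodes), value),
        sigma=np.full(120, 0.2),
        field_sd=np.full(120, 1.0),
        field_range=np.full(120, 0.5),
        temporal_rho=np.full(120, 0.5),
        grid=grid,
    )


class TestPredictStack:
    def test_degenerate_posterior_zero_width(self):
        grid = make_grid(4, 4, 2)
        post = _degenerate_posterior(grid, 0.3)
        m_pix = np.full((grid.n_pixels * 2, 2), 0.6)
        surf = predict_stack(post, m_pix, grid)
        expected = inverse_transform(0.5 * 0.6 + 0.5 * 0.6 + 0.3)
        assert np.allclose(surf.mean, expected, atol=1e-12)
        assert np.allclose(surf.ci_width, 0.0, atol=1e-12)

    def test_ci_brackets_mean(self):
        y, m, node, grid, params = _toy_fit_inputs()
        post = fit_stack(y, m, node, grid, seed=0, n_draws=300, fixed_params=params)
        m_pix = np.zeros((grid.n_pixels * grid.n_years, 2))
        surf = predict_stack(post, m_pix, grid)
        assert np.all(surf.lower <= surf.mean + 1e-9)
        assert np.all(surf.mean <= surf.upper + 1e-9)
        assert np.all(surf.mean >= 0) and np.all(surf.mean <= 1)

    def test_few_draws_warns(self):
        grid = make_grid(3, 3, 1)
        post = _degenerate_posterior(grid, 0.0)
        post.weights = post.weights[:50]
        post.field = post.field[:50]
        post.sigma = post.sigma[:50]
        with pytest.warns(UserWarning, match="draws"):
            predict_stack(post, np.zeros((9, 2)), grid)

    def test_sparse_region_has_wider_ci(self):
        # data clustered in the NW corner; far (SE) pixel CI >= dense-pixel CI
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            grid = make_grid(10, 10, 2)
            n = 100
            # cluster nodes among the first 3 rows/cols
            rows = rng.integers(0, 3, n)
            cols = rng.integers(0, 3, n)
            t = rng.integers(0, 2, n)
            node = (rows * 10 + cols) * 2 + t
            m = rng.standard_normal((n, 2))
            f = gmrf.sample_field(10, 10, 2, 4.0, 0.8, 0.5, rng)[0].ravel()
            y = m @ np.array([0.6, 0.4]) + f[node] + 0.3 * rng.standard_normal(n)
            params = dict(field_sd=0.8, field_range=1.0, temporal_rho=0.5, sigma=0.3)
            post = fit_stack(y, m, node, grid, seed=seed, n_draws=150, fixed_params=params)
            m_pix = np.zeros((grid.n_pixels * 2, 2))
            surf = predict_stack(post, m_pix, grid)
            dense_px = surf.ci_width[0, 1, 1]
            far_px = surf.ci_width[0, 9, 9]
            if far_px >= dense_px:
                wins += 1
        assert wins >= 9


class TestPredictiveDensity:
    def test_pit_half_at_predictive_mean(self):
        grid = make_grid(3, 3, 1)
        post = _degenerate_posterior(grid, 0.1)
        m_row = np.array([0.2, 0.2])
        mean, var, pit = predictive_density(post, m_row, node=4, y_obs=0.5 * 0.4 + 0.1)
        assert pit == pytest.approx(0.5, abs=1e-12)
        assert mean == pytest.approx(0.3, abs=1e-12)

    def test_predictive_variance_at_least_noise(self):
        y, m, node, grid, params = _toy_fit_inputs()
        post = fit_stack(y, m, node, grid, seed=0, n_draws=200, fixed_params=params)
        _, var, _ = predictive_density(post, m[0], int(node[0]), y[0])
        assert var >= np.mean(post.sigma**2) - 1e-12

    def test_pit_uniform_on_held_out(self):
        # correctly specified small fit; KS distance from uniform is small
        rng = np.random.default_rng(11)
        grid = make_grid(8, 8, 3)
        n_all = 400
        node = rng.integers(0, grid.n_pixels * 3, n_all)
        m = rng.standard_normal((n_all, 2))
        params = dict(field_sd=0.8, field_range=0.8, temporal_rho=0.6, sigma=0.35)
        f = gmrf.sample_field(8, 8, 3, params["field_range"] / grid.cell_size,
                              params["field_sd"], params["temporal_rho"], rng)[0].ravel()
        y = m @ np.array([0.6, 0.4]) + f[node] + params["sigma"] * rng.standard_normal(n_all)
        train, test = slice(0, 250), slice(250, 400)
        post = fit_stack(y[train], m[train], node[train], grid, seed=0, n_draws=300,
                         fixed_params=params)
        pits = [predictive_density(post, m[i], int(node[i]), y[i])[2] for i in range(250, 400)]
        assert kstest(pits, "uniform").statistic < 0.12
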