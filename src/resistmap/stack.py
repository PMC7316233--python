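"""Level-1 Bayesian Gaussian-process meta-model.

Transformed observations are regressed on the out-of-fold level-0
predictions with nonnegative weights, plus a separable spatiotemporal GMRF
and i.i.d. Gaussian noise:

    y_i = w . M_i + f(node_i) + e_i,   e_i ~ N(0, sigma^2),  w >= 0.

Inference is a deterministic approximation in the style of integrated nested
Laplace approximations: conditional on the four hyperparameters
(field sd, spatial range, temporal AR(1) rho, noise sd) the model is
linear-Gaussian and the posterior of (w, f) is available in closed form via
sparse linear algebra.  The hyperparameter posterior is explored by Laplace
approximation at the mode followed by self-normalised importance sampling;
joint draws are produced by sampling hyperparameters and then exact Gaussian
conditionals (perturbation sampling).  With hyperparameters fixed and the
positivity constraint inactive the posterior mean is exact Gaussian
conditioning, which is what the oracle tests check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.stats import norm

from resistmap import gmrf
from resistmap.datamodel import GridDefinition
from resistmap.transforms import DEFAULT_N_REF, DEFAULT_SMOOTHING, inverse_transform

__all__ = ["StackPriors", "StackPosterior", "PredictionSurface", "fit_stack", "predict_stack", "predictive_density"]


@dataclass
class StackPriors:
    """Weakly informative default priors for the meta-model hyperparameters."""

    sd_scale: float = 2.0  # half-normal scale for the field marginal sd
    sigma_scale: float = 2.0  # half-normal scale for the noise sd
    range_mode: float | None = None  # log-normal centre for the range (deg); None = 1/4 of domain extent
    range_log_sd: float = 1.5
    weight_sd: float = 1e4  # near-flat Gaussian prior on weights


@dataclass
class StackPosterior:
    """Posterior draws of the meta-model: weights, field parameters, noise,
    and the latent field at every grid node (pixel x year)."""

    weights: np.ndarray  # (n_draws, p), all >= 0 when constrained
    field: np.ndarray  # (n_draws, n_nodes)
    sigma: np.ndarray  # (n_draws,)
    field_sd: np.ndarray
    field_range: np.ndarray  # degrees
    temporal_rho: np.ndarray
    grid: GridDefinition
    diagnostics: dict = field(default_factory=dict)
    # Exact conditional means, populated when hyperparameters are fixed.
    cond_mean_weights: np.ndarray | None = None
    cond_mean_field: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return len(self.sigma)

    @property
    def n_models(self) -> int:
        return self.weights.shape[1]

    def weight_mean(self) -> np.ndarray:
        return self.weights.mean(axis=0)

    def summary(self) -> dict:
        def ci(a):
            return {
                "mean": float(np.mean(a)),
                "q2.5": float(np.percentile(a, 2.5)),
                "q97.5": float(np.percentile(a, 97.5)),
            }

        out = {f"w[{j}]": ci(self.weights[:, j]) for j in range(self.n_models)}
        out["sigma"] = ci(self.sigma)
        out["field_sd"] = ci(self.field_sd)
        out["field_range"] = ci(self.field_range)
        out["temporal_rho"] = ci(self.temporal_rho)
        return out


@dataclass
class PredictionSurface:
    """Per-pixel, per-year posterior summaries on the natural mortality scale."""

    mean: np.ndarray  # (n_years, n_rows, n_cols)
    lower: np.ndarray
    upper: np.ndarray
    grid: GridDefinition

    @property
    def ci_width(self) -> np.ndarray:
        return self.upper - self.lower


def _field_chol(grid: GridDefinition, range_deg: float):
    range_cells = max(range_deg / grid.cell_size, 1.0)
    q_s, ld_s = gmrf.spatial_precision(grid.n_rows, grid.n_cols, range_cells)
    l_s = cholesky(q_s.toarray(), lower=True)
    return q_s, ld_s, l_s


class _System:
    """Linear-Gaussian system for one hyperparameter setting.

    The sparse solve only involves the field block P_f = Q + A^T A / sigma^2
    (pure GMRF sparsity); the p weight coordinates are handled through a
    dense p x p Schur complement, avoiding the catastrophic LU fill-in that
    the dense weight rows would otherwise cause.
    """

    def __init__(self, theta: np.ndarray, model: "_StackModel"):
        sd, range_deg, rho, sigma = np.exp(theta[0]), np.exp(theta[1]), np.tanh(theta[2]), np.exp(theta[3])
        self.sd, self.range_deg, self.rho, self.sigma = sd, range_deg, rho, sigma
        m = model
        grid = m.grid
        range_cells = max(range_deg / grid.cell_size, 1.0)
        q_s, ld_s = gmrf.spatial_precision(grid.n_rows, grid.n_cols, range_cells)
        q_t, ld_t = gmrf.ar1_precision(grid.n_years, rho)
        n_s, n_t = grid.n_pixels, grid.n_years
        q = sp.kron(q_s, q_t, format="csc") / sd**2
        ld_q = n_t * ld_s + n_s * ld_t - 2.0 * n_s * n_t * np.log(sd)
        p = m.n_models
        tau2 = m.priors.weight_sd**2
        ld_prior = ld_q - p * np.log(tau2)
        s2 = sigma**2

        # Field block and its factorisation.
        p_f = (q + sp.diags(m.node_counts) / s2).tocsc()
        self.factor_f = splu(p_f, permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True))
        ld_pf = float(np.sum(np.log(np.abs(self.factor_f.U.diagonal()))))

        # Schur complement on the weights: S_w = P_w - C P_f^{-1} C^T,
        # with P_w = I/tau^2 + M^T M / s2 and C = M^T A / s2.
        c_t = m.at_m / s2  # (n_nodes, p) sparse
        c_dense = c_t.toarray()
        pfinv_ct = self.factor_f.solve(c_dense)  # (n_nodes, p)
        p_w = np.eye(p) / tau2 + m.mtm / s2
        s_w = p_w - c_dense.T @ pfinv_ct
        self.s_w = 0.5 * (s_w + s_w.T)
        sign, ld_sw = np.linalg.slogdet(self.s_w)
        ld_post = ld_pf + float(ld_sw)

        # Posterior mean via block solves.
        b_w = m.mty / s2
        b_f = m.aty / s2
        pfinv_bf = self.factor_f.solve(b_f)
        self.mean_w = np.linalg.solve(self.s_w, b_w - c_dense.T @ pfinv_bf)
        self.mean_f = pfinv_bf - pfinv_ct @ self.mean_w
        self._pfinv_ct = pfinv_ct
        self._c_dense = c_dense
        self._s_w_chol_cache: np.ndarray | None = None

        n = m.n_obs
        b_dot_mu = float(b_w @ self.mean_w + b_f @ self.mean_f)
        self.log_marginal = float(
            0.5 * (ld_prior - ld_post)
            - 0.5 * n * np.log(2 * np.pi * s2)
            - 0.5 * (m.yty / s2 - b_dot_mu)
        )
        self._l_s = None
        self._l_t = None

    @property
    def mean(self) -> np.ndarray:
        return np.concatenate([self.mean_w, self.mean_f])

    def draw_weights(self, rng: np.random.Generator) -> np.ndarray:
        """w | y ~ N(mean_w, S_w^{-1})."""
        if self._s_w_chol_cache is None:
            self._s_w_chol_cache = cholesky(self.s_w, lower=True)
        eps = rng.standard_normal(len(self.mean_w))
        return self.mean_w + solve_triangular(self._s_w_chol_cache.T, eps, lower=False)

    def draw_field(self, w: np.ndarray, model: "_StackModel", rng: np.random.Generator) -> np.ndarray:
        """f | w, y ~ N(P_f^{-1}(b_f - C^T w), P_f^{-1}) by perturbation sampling."""
        m = model
        if self._l_s is None:
            range_cells = max(self.range_deg / m.grid.cell_size, 1.0)
            q_s, _ = gmrf.spatial_precision(m.grid.n_rows, m.grid.n_cols, range_cells)
            q_t, _ = gmrf.ar1_precision(m.grid.n_years, self.rho)
            self._l_s = cholesky(q_s.toarray(), lower=True)
            self._l_t = cholesky(q_t.toarray(), lower=True)
        n_s, n_t = m.grid.n_pixels, m.grid.n_years
        s2 = self.sigma**2
        eps = rng.standard_normal((n_s, n_t))
        v_f = (self._l_s @ eps @ self._l_t.T).ravel() / self.sd  # ~ N(0, Q)
        eps_y = rng.standard_normal(m.n_obs)
        resid = m.y - m.m @ w + self.sigma * eps_y
        b = np.zeros(n_s * n_t)
        np.add.at(b, m.node_index, resid / s2)
        return self.factor_f.solve(b + v_f)

    def draw(self, model: "_StackModel", rng: np.random.Generator) -> np.ndarray:
        w = self.draw_weights(rng)
        f = self.draw_field(w, model, rng)
        return np.concatenate([w, f])


class _StackModel:
    """Data, design and priors shared across hyperparameter evaluations."""

    def __init__(self, y, oof_matrix, node_index, grid, priors):
        self.y = np.asarray(y, dtype=float)
        self.m = np.asarray(oof_matrix, dtype=float)
        self.node_index = np.asarray(node_index, dtype=int)
        self.grid = grid
        self.priors = priors
        self.n_obs, self.n_models = self.m.shape
        n_nodes = grid.n_pixels * grid.n_years
        a = sp.csr_matrix(
            (np.ones(self.n_obs), (np.arange(self.n_obs), self.node_index)),
            shape=(self.n_obs, n_nodes),
        )
        self.node_counts = np.asarray(a.sum(axis=0)).ravel()  # diag of A^T A
        self.at_m = (a.T @ sp.csr_matrix(self.m)).tocsc()  # (n_nodes, p)
        self.mtm = self.m.T @ self.m
        self.mty = self.m.T @ self.y
        self.aty = a.T @ self.y
        self.yty = float(self.y @ self.y)

    def log_prior(self, theta: np.ndarray) -> float:
        sd, rho, sigma = np.exp(theta[0]), np.tanh(theta[2]), np.exp(theta[3])
        pr = self.priors
        lp = -0.5 * sd**2 / pr.sd_scale**2 + theta[0]  # half-normal + log-scale Jacobian
        lp += -0.5 * sigma**2 / pr.sigma_scale**2 + theta[3]
        r0 = pr.range_mode
        if r0 is None:
            extent = max(self.grid.n_rows, self.grid.n_cols) * self.grid.cell_size
            r0 = 0.25 * extent
        lp += -0.5 * (theta[1] - np.log(r0)) ** 2 / pr.range_log_sd**2
        lp += np.log1p(-rho**2)  # uniform(-1,1) through tanh
        return float(lp)

    def log_post(self, theta: np.ndarray) -> float:
        try:
            sys = _System(theta, self)
        except (np.linalg.LinAlgError, RuntimeError, ValueError):
            return -np.inf
        return sys.log_marginal + self.log_prior(theta)


def _laplace_importance(
    model: _StackModel, seed: int, n_is: int, theta0: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Mode-finding + Gaussian/t importance sampling over hyperparameters.

    Returns (theta samples, normalised importance weights, diagnostics).
    """
    neg = lambda th: -model.log_post(th)
    res = minimize(neg, theta0, method="Nelder-Mead", options={"maxfev": 120, "xatol": 0.02, "fatol": 0.02})
    mode = res.x
    # Finite-difference Hessian of the negative log posterior at the mode.
    d = len(mode)
    h = 0.12
    hess = np.zeros((d, d))
    f0 = neg(mode)
    for i in range(d):
        for j in range(i, d):
            ei = np.eye(d)[i] * h
            ej = np.eye(d)[j] * h
            if i == j:
                hess[i, i] = (neg(mode + ei) - 2 * f0 + neg(mode - ei)) / h**2
            else:
                hess[i, j] = hess[j, i] = (
                    neg(mode + ei + ej) - neg(mode + ei - ej) - neg(mode - ei + ej) + neg(mode - ei - ej)
                ) / (4 * h**2)
    # Regularise to SPD.
    evals, evecs = np.linalg.eigh(hess)
    evals = np.clip(evals, 1e-2, None)
    cov = (evecs / evals) @ evecs.T
    scale_chol = cholesky(cov * 1.4, lower=True)

    rng = np.random.default_rng(seed)
    df = 7.0
    z = rng.standard_normal((n_is, d))
    g = rng.chisquare(df, size=n_is) / df
    thetas = mode + (z / np.sqrt(g)[:, None]) @ scale_chol.T
    # log density of the multivariate t proposal (constants cancel in weights)
    delta = thetas - mode
    sol = solve_triangular(scale_chol, delta.T, lower=True)
    maha = np.sum(sol**2, axis=0)
    log_q = -0.5 * (df + d) * np.log1p(maha / df)
    log_p = np.array([model.log_post(t) for t in thetas])
    lw = log_p - log_q
    lw -= lw.max()
    w = np.exp(lw)
    w /= w.sum()
    ess = 1.0 / np.sum(w**2)
    diag = {"mode": mode, "ess": float(ess), "opt_success": bool(res.success), "n_is": n_is}
    return thetas, w, diag


def fit_stack(
    y: np.ndarray,
    oof_matrix: np.ndarray,
    node_index: np.ndarray,
    grid: GridDefinition,
    priors: StackPriors | None = None,
    seed: int = 0,
    n_draws: int = 200,
    n_is: int = 100,
    fixed_params: dict | None = None,
    constrain_weights: bool = True,
) -> StackPosterior:
    """Fit the meta-model and return posterior draws.

    Parameters
    ----------
    y : transformed labels, length n.
    oof_matrix : (n, p) out-of-fold level-0 predictions (the stacking design).
    node_index : per observation, pixel * n_years + year-index on ``grid``.
    grid : the prediction grid (field support).
    fixed_params : optional dict with keys ``field_sd``, ``field_range``,
        ``temporal_rho``, ``sigma``; skips hyperparameter inference and
        conditions exactly on these values.
    constrain_weights : enforce w >= 0 on the draws (rejection, then
        projection as a last resort).
    """
    priors = priors or StackPriors()
    model = _StackModel(y, oof_matrix, node_index, grid, priors)
    if model.n_models < 2:
        raise ValueError("need at least 2 level-0 models to stack")
    # Rank check of the stacking design.
    sv = np.linalg.svd(model.m, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        warnings.warn("stacking design is rank deficient (all-equal model predictions?); weights are unidentifiable")

    rng = np.random.default_rng(seed)
    p = model.n_models

    if fixed_params is not None:
        theta = np.array(
            [
                np.log(fixed_params["field_sd"]),
                np.log(fixed_params["field_range"]),
                np.arctanh(fixed_params["temporal_rho"]),
                np.log(fixed_params["sigma"]),
            ]
        )
        thetas = np.tile(theta, (1, 1))
        w_is = np.array([1.0])
        diag = {"fixed": True}
    else:
        ols_resid = model.y - model.m @ np.linalg.lstsq(model.m, model.y, rcond=None)[0]
        s0 = max(float(np.std(ols_resid)), 1e-3)
        extent = max(grid.n_rows, grid.n_cols) * grid.cell_size
        theta0 = np.array([np.log(s0 * 0.8), np.log(0.25 * extent), np.arctanh(0.5), np.log(s0 * 0.6)])
        thetas, w_is, diag = _laplace_importance(model, seed, n_is, theta0)

    # Resample hyperparameter draws by importance weight.
    idx = rng.choice(len(thetas), size=n_draws, replace=True, p=w_is)
    systems: dict[int, _System] = {}
    weights = np.empty((n_draws, p))
    fields = np.empty((n_draws, grid.n_pixels * grid.n_years))
    sigma = np.empty(n_draws)
    fsd = np.empty(n_draws)
    frange = np.empty(n_draws)
    frho = np.empty(n_draws)
    n_projected = 0
    for d, i in enumerate(idx):
        i = int(i)
        if i not in systems:
            systems[i] = _System(thetas[i], model)
        sys = systems[i]
        w_draw = sys.draw_weights(rng)
        if constrain_weights:
            tries = 0
            while np.any(w_draw < 0) and tries < 100:
                w_draw = sys.draw_weights(rng)
                tries += 1
            if np.any(w_draw < 0):
                w_draw = np.clip(w_draw, 0.0, None)
                n_projected += 1
        weights[d] = w_draw
        fields[d] = sys.draw_field(w_draw, model, rng)
        sigma[d] = sys.sigma
        fsd[d] = sys.sd
        frange[d] = sys.range_deg
        frho[d] = sys.rho
    diag["n_projected"] = n_projected

    post = StackPosterior(
        weights=weights, field=fields, sigma=sigma, field_sd=fsd,
        field_range=frange, temporal_rho=frho, grid=grid, diagnostics=diag,
    )
    if fixed_params is not None:
        sys = systems[0] if 0 in systems else _System(thetas[0], model)
        post.cond_mean_weights = sys.mean[:p].copy()
        post.cond_mean_field = sys.mean[p:].copy()
    return post


def predict_stack(
    posterior: StackPosterior,
    insample_pixel_matrix: np.ndarray,
    grid: GridDefinition,
    years: list[int] | None = None,
    n_draws: int | None = None,
    c: float = DEFAULT_SMOOTHING,
    n_ref: int = DEFAULT_N_REF,
) -> PredictionSurface:
    """Posterior prediction surfaces of mean proportional mortality.

    ``insample_pixel_matrix`` has shape (n_nodes, p): the level-0 in-sample
    predictions evaluated at every grid node (pixel x year, node index =
    pixel * n_years + t).  Per posterior draw the linear predictor
    w . M + f is back-transformed to the natural scale; the mean and the
    2.5/97.5 percentiles are taken over draws.  The noise term is excluded:
    surfaces map mean resistance, not single-test outcomes.
    """
    years = list(years) if years is not None else list(grid.years)
    n_use = posterior.n_draws if n_draws is None else min(n_draws, posterior.n_draws)
    if n_use < 100:
        warnings.warn(f"only {n_use} posterior draws; credible intervals may be unstable")
    m = np.asarray(insample_pixel_matrix, dtype=float)
    n_nodes = grid.n_pixels * grid.n_years
    if m.shape != (n_nodes, posterior.n_models):
        raise ValueError(f"insample matrix shape {m.shape} != ({n_nodes}, {posterior.n_models})")
    draws = np.empty((n_use, n_nodes))
    for d in range(n_use):
        g = m @ posterior.weights[d] + posterior.field[d]
        draws[d] = inverse_transform(g, c=c, n_ref=n_ref)
    mean = draws.mean(axis=0)
    lower = np.percentile(draws, 2.5, axis=0)
    upper = np.percentile(draws, 97.5, axis=0)

    def to_cube(v):
        return v.reshape(grid.n_pixels, grid.n_years).T.reshape(grid.n_years, grid.n_rows, grid.n_cols)

    t_sel = [grid.year_index(yr) for yr in years]
    sub = GridDefinition(
        origin_lon=grid.origin_lon, origin_lat=grid.origin_lat, cell_size=grid.cell_size,
        n_cols=grid.n_cols, n_rows=grid.n_rows, years=years, mask=grid.mask,
    )
    return PredictionSurface(
        mean=to_cube(mean)[t_sel], lower=to_cube(lower)[t_sel], upper=to_cube(upper)[t_sel], grid=sub,
    )


def prediction_draws(
    posterior: StackPosterior,
    insample_pixel_matrix: np.ndarray,
    grid: GridDefinition,
    c: float = DEFAULT_SMOOTHING,
    n_ref: int = DEFAULT_N_REF,
) -> np.ndarray:
    """All draw-level natural-scale surfaces, shape (n_draws, n_years, n_rows, n_cols)."""
    m = np.asarray(insample_pixel_matrix, dtype=float)
    out = np.empty((posterior.n_draws, grid.n_years, grid.n_rows, grid.n_cols))
    for d in range(posterior.n_draws):
        g = m @ posterior.weights[d] + posterior.field[d]
        p = inverse_transform(g, c=c, n_ref=n_ref)
        out[d] = p.reshape(grid.n_pixels, grid.n_years).T.reshape(grid.n_years, grid.n_rows, grid.n_cols)
    return out


def predictive_density(
    posterior: StackPosterior,
    m_row: np.ndarray,
    node: int,
    y_obs: float,
) -> tuple[float, float, float]:
    """Predictive distribution of a NEW observation's transformed label.

    The predictive includes the measurement-noise variance sigma^2 (a new
    test is a noisy draw around the latent surface).  Returns
    (predictive mean, predictive variance, PIT value) where the PIT value is
    the posterior-predictive CDF evaluated at ``y_obs``.
    """
    mu = posterior.weights @ np.asarray(m_row, dtype=float) + posterior.field[:, node]
    pred_mean = float(mu.mean())
    pred_var = float(mu.var() + np.mean(posterior.sigma**2))
    pit = float(np.mean(norm.cdf(y_obs, loc=mu, scale=posterior.sigma)))
    return pred_mean, pred_var, pit
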