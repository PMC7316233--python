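"""Reproducibility experiments: self-contained, seeded computations behind
the acceptance checks (oracle equivalence, parameter recovery, weight
recovery, ensemble improvement, calibration, transform round-trips, summary
brute-force agreement, pipeline determinism).

Every function draws all randomness from its ``seed`` argument and returns a
plain dict of numbers, so the same code backs both the test suite and the
standalone acceptance report.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kstest

from resistmap import gmrf
from resistmap.datamodel import BioassayObservation, GridDefinition
from resistmap.ensemble import FeatureBuilder, fit_ensemble
from resistmap.stack import StackPriors, fit_stack, predictive_density
from resistmap.summaries import area_below_threshold, interannual_change, weighted_importance
from resistmap.synthetic import SimulationConfig, simulate_covariates, simulate_observations, simulate_true_surface
from resistmap.transforms import inverse_transform, transform
from resistmap.validation import ci_coverage

FAST_SPECS = [
    ("boosted_trees", {"n_estimators": 30, "max_depth": 3}),
    ("random_forest", {"n_estimators": 40}),
    ("additive_boost", {"n_iter": 60}),
]


def _grid(n_rows: int, n_cols: int, n_years: int, cell: float = 0.25) -> GridDefinition:
    return GridDefinition(
        origin_lon=0.0, origin_lat=n_rows * cell, cell_size=cell,
        n_cols=n_cols, n_rows=n_rows, years=list(range(2005, 2005 + n_years)),
    )


def _simulate_from_meta_model(rng, grid, n, params, w_true):
    """Draw (y, M, node) exactly from the meta-model's data-generating process."""
    n_nodes = grid.n_pixels * grid.n_years
    node = rng.integers(0, n_nodes, n)
    m = rng.standard_normal((n, len(w_true)))
    f = gmrf.sample_field(
        grid.n_rows, grid.n_cols, grid.n_years,
        params["field_range"] / grid.cell_size, params["field_sd"], params["temporal_rho"], rng,
    )[0].ravel()
    y = m @ w_true + f[node] + params["sigma"] * rng.standard_normal(n)
    return y, m, node


def oracle_equivalence(seed: int = 0) -> dict:
    """Max relative error of the fixed-hyperparameter posterior mean against
    dense closed-form Gaussian conditioning on a 40-observation instance."""
    rng = np.random.default_rng(seed)
    grid = _grid(5, 5, 2)
    params = dict(field_sd=0.8, field_range=0.7, temporal_rho=0.5, sigma=0.3)
    w_true = np.array([0.7, 0.4])
    y, m, node = _simulate_from_meta_model(rng, grid, 40, params, w_true)
    post = fit_stack(y, m, node, grid, seed=seed, n_draws=20, fixed_params=params,
                     constrain_weights=False)

    # Dense oracle over the full joint [w, f].
    q, _ = gmrf.space_time_precision(
        grid.n_rows, grid.n_cols, grid.n_years,
        params["field_range"] / grid.cell_size, params["field_sd"], params["temporal_rho"],
    )
    n_nodes = q.shape[0]
    a = np.zeros((len(y), n_nodes))
    a[np.arange(len(y)), node] = 1.0
    b = np.hstack([m, a])
    tau = StackPriors().weight_sd
    prior = np.zeros((2 + n_nodes, 2 + n_nodes))
    prior[:2, :2] = np.eye(2) / tau**2
    prior[2:, 2:] = q.toarray()
    post_prec = prior + b.T @ b / params["sigma"] ** 2
    mean = np.linalg.solve(post_prec, b.T @ y / params["sigma"] ** 2)
    w_err = np.max(np.abs(post.cond_mean_weights - mean[:2]) / np.abs(mean[:2]))
    f_scale = np.max(np.abs(mean[2:]))
    f_err = np.max(np.abs(post.cond_mean_field - mean[2:])) / f_scale
    return {"weight_max_rel_err": float(w_err), "field_max_rel_err": float(f_err), "n": len(y)}


RECOVERY_TRUTH = {
    "w0": 0.6, "w1": 0.3, "w2": 0.2,
    "field_sd": 1.0, "field_range": 1.2, "temporal_rho": 0.7, "sigma": 0.4,
}


def parameter_recovery(n_replicates: int = 20, seed: int = 0, n_obs: int = 800,
                       n_draws: int = 300, n_is: int = 100) -> dict:
    """Coverage of posterior 95% intervals over replicate synthetic fits
    (20 x 20 grid, 6 years) with known weights and field parameters."""
    grid = _grid(20, 20, 6)
    truth = RECOVERY_TRUTH
    params = dict(field_sd=truth["field_sd"], field_range=truth["field_range"],
                  temporal_rho=truth["temporal_rho"], sigma=truth["sigma"])
    w_true = np.array([truth["w0"], truth["w1"], truth["w2"]])
    hits = {k: 0 for k in truth}
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed * 10_000 + rep)
        y, m, node = _simulate_from_meta_model(rng, grid, n_obs, params, w_true)
        post = fit_stack(y, m, node, grid, seed=seed * 10_000 + rep + 1,
                         n_draws=n_draws, n_is=n_is)
        draws = {
            "w0": post.weights[:, 0], "w1": post.weights[:, 1], "w2": post.weights[:, 2],
            "field_sd": post.field_sd, "field_range": post.field_range,
            "temporal_rho": post.temporal_rho, "sigma": post.sigma,
        }
        for k, d in draws.items():
            lo, hi = np.percentile(d, [2.5, 97.5])
            if lo <= truth[k] <= hi:
                hits[k] += 1
    return {
        "coverage": {k: hits[k] / n_replicates for k in truth},
        "min_coverage": min(hits.values()) / n_replicates,
        "n_replicates": n_replicates,
        "n_obs": n_obs,
    }


def weight_recovery(seed: int = 0) -> dict:
    """One level-0 column equals truth plus small noise, the other is pure
    noise; report the posterior mean weights."""
    rng = np.random.default_rng(seed)
    grid = _grid(6, 6, 2)
    n = 120
    node = rng.integers(0, grid.n_pixels * 2, n)
    truth = rng.standard_normal(n)
    m = np.column_stack([truth + 0.01 * rng.standard_normal(n), rng.standard_normal(n)])
    params = dict(field_sd=1e-3, field_range=0.5, temporal_rho=0.1, sigma=0.1)
    post = fit_stack(truth, m, node, grid, seed=seed, n_draws=200, fixed_params=params)
    w = post.weight_mean()
    return {"truth_column_weight": float(w[0]), "noise_column_weight": float(w[1]), "n": n}


def ensemble_improvement(n_replicates: int = 20, seed: int = 0) -> dict:
    """Out-of-sample RMSE of the stacked predictor vs each constituent on
    full synthetic-pipeline replicates (covariates -> truth -> binomial
    observations -> level-0 -> meta-model)."""
    wins = 0
    stacked_rmses, best_const_rmses = [], []
    for rep in range(n_replicates):
        rep_seed = seed * 10_000 + 137 * rep
        rng = np.random.default_rng(rep_seed)
        grid = _grid(15, 15, 4)
        cfg = SimulationConfig(
            grid=grid, n_covariates=3, field_sd=0.7, field_range=1.0, temporal_rho=0.7,
            noise_sd=0.25, weight_truth=(0.8, 0.5), n_sites=130, obs_per_site=2,
            intercept=1.2, trend=-0.2, vgsc_fraction=0.08, seed=rep_seed,
        )
        cov = simulate_covariates(grid, 3, seed=rep_seed)
        truth = simulate_true_surface(cfg, covariates=cov)
        bio, allele = simulate_observations(truth, cfg)
        builder = FeatureBuilder(cov)
        fm = builder.build(bio, allele)
        is_bio = fm.source_kind == "bioassay"
        bio_idx = np.flatnonzero(is_bio)
        test_bio = rng.choice(bio_idx, size=len(bio_idx) // 4, replace=False)
        test = np.zeros(len(fm), dtype=bool)
        test[test_bio] = True
        train_fm = fm.subset(~test)
        ens = fit_ensemble(train_fm, model_specs=FAST_SPECS, k=4, seed=rep_seed)
        m_test = ens.predict(fm.x[test])
        const = np.sqrt(np.mean((fm.y[test][:, None] - m_test) ** 2, axis=0))
        tr_bio = train_fm.source_kind == "bioassay"
        post = fit_stack(
            train_fm.y[tr_bio], ens.oof_matrix[tr_bio], train_fm.node_index[tr_bio],
            grid, seed=rep_seed + 1, n_draws=100, n_is=40,
        )
        mu = post.weights @ m_test.T + post.field[:, fm.node_index[test]]
        stacked = float(np.sqrt(np.mean((mu.mean(axis=0) - fm.y[test]) ** 2)))
        stacked_rmses.append(stacked)
        best_const_rmses.append(float(const.min()))
        if stacked <= const.min():
            wins += 1
    return {
        "wins": wins,
        "n_replicates": n_replicates,
        "win_fraction": wins / n_replicates,
        "mean_stacked_rmse": float(np.mean(stacked_rmses)),
        "mean_best_constituent_rmse": float(np.mean(best_const_rmses)),
    }


def calibration(seed: int = 0, n_train: int = 400, n_test: int = 500) -> dict:
    """95% predictive-interval coverage (noise included) and PIT uniformity
    on held-out observations from a correctly specified fit."""
    rng = np.random.default_rng(seed)
    grid = _grid(15, 15, 5)
    params = dict(field_sd=0.8, field_range=1.0, temporal_rho=0.6, sigma=0.35)
    w_true = np.array([0.6, 0.4])
    y, m, node = _simulate_from_meta_model(rng, grid, n_train + n_test, params, w_true)
    post = fit_stack(y[:n_train], m[:n_train], node[:n_train], grid, seed=seed,
                     n_draws=200, n_is=50)
    means = np.empty(n_test)
    lat_var = np.empty(n_test)
    noise_var = np.empty(n_test)
    pits = np.empty(n_test)
    for i in range(n_test):
        j = n_train + i
        mu = post.weights @ m[j] + post.field[:, node[j]]
        means[i] = mu.mean()
        lat_var[i] = mu.var()
        noise_var[i] = np.mean(post.sigma**2)
        pits[i] = predictive_density(post, m[j], int(node[j]), y[j])[2]
    cov = ci_coverage(means, lat_var, noise_var, y[n_train:], include_noise=True)
    ks = float(kstest(pits, "uniform").statistic)
    return {"coverage_95": cov[0.95], "coverage_80": cov[0.8], "coverage_50": cov[0.5],
            "pit_ks": ks, "n_held_out": n_test}


def transform_correctness(n_ref: int = 100) -> dict:
    """Transform-chain agreement with an independently composed high-precision
    oracle, and the inverse round-trip error bound."""
    errs = []
    obs = BioassayObservation(site_id="s", lon=0.5, lat=0.5, year=2005,
                              insecticide="DDT", protocol="WHO", n_tested=25, mortality=1.0)
    got = transform(obs, c=0.5).value
    errs.append(abs(got - math.asinh(math.log(25.5 / 0.5))))
    for k, n in [(0, 10), (5, 10), (17, 60)]:
        o = BioassayObservation(site_id="s", lon=0.5, lat=0.5, year=2005,
                                insecticide="DDT", protocol="WHO", n_tested=n, mortality=k / n)
        expected = math.asinh(math.log((k + 0.5) / (n - k + 0.5)))
        errs.append(abs(transform(o, c=0.5).value - expected))
    round_trip = []
    for p in np.arange(0.1, 0.95, 0.1):
        o = BioassayObservation(site_id="s", lon=0.5, lat=0.5, year=2005,
                                insecticide="DDT", protocol="WHO", n_tested=n_ref,
                                mortality=round(p, 2))
        back = inverse_transform(transform(o).value, n_ref=n_ref)
        round_trip.append(abs(back - round(p, 2)))
    return {
        "chain_max_abs_err": float(max(errs)),
        "round_trip_max_err": float(max(round_trip)),
        "round_trip_bound": 1.0 / (2 * n_ref),
        "n_ref": n_ref,
    }


def summary_correctness(seed: int = 0) -> dict:
    """Max absolute deviation of the summary operations from brute-force
    enumeration on small random fixtures."""
    rng = np.random.default_rng(seed)
    draws = rng.uniform(size=(40, 2, 3, 3))
    mask = np.ones((3, 3), bool)
    trend = area_below_threshold(draws, mask, [2005, 2006], threshold=0.9)
    brute = np.array([
        [np.mean(draws.mean(axis=0)[t][mask] < 0.9) for t in range(2)],
    ]).ravel()
    err_area = np.max(np.abs(trend.table["proportion"].to_numpy() - brute))

    series = rng.uniform(size=(6, 2, 2))
    inc, dec = interannual_change(series)
    err_change = 0.0
    for r in range(2):
        for c in range(2):
            diffs = np.diff(series[:, r, c])
            err_change = max(err_change, abs(inc[r, c] - max(diffs.max(), 0.0)))
            err_change = max(err_change, abs(dec[r, c] - max((-diffs).max(), 0.0)))

    imp = pd.DataFrame(rng.dirichlet(np.ones(4), size=3), index=["m1", "m2", "m3"],
                       columns=["f1", "f2", "f3", "f4"])
    w = {"m1": 0.5, "m2": 0.3, "m3": 0.2}
    out = weighted_importance(imp, w)
    err_imp = 0.0
    for f in imp.columns:
        expected = sum(w[m] * imp.loc[m, f] for m in imp.index)
        err_imp = max(err_imp, abs(out.loc[f, "total"] - expected))
    return {
        "area_max_abs_err": float(err_area),
        "interannual_max_abs_err": float(err_change),
        "weighted_importance_max_abs_err": float(err_imp),
    }


def pipeline_determinism(seed: int = 0, config_path: str | Path | None = None,
                         work_dir: str | Path | None = None) -> dict:
    """Run the bundled synthetic pipeline twice with identical seeds and
    byte-compare the summary tables."""
    import tempfile

    import yaml

    from resistmap.pipeline import run_pipeline

    if config_path is None:
        config_path = Path(__file__).resolve().parents[2] / "examples" / "small.yml"
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    cfg["seed"] = int(seed)
    tables = ["threshold_area_trend.csv", "stack_weights.csv", "level0_importances.csv",
              "level0_oof_matrix.csv", "weighted_importance.csv"]
    ctx = tempfile.TemporaryDirectory() if work_dir is None else None
    base = Path(ctx.name) if ctx else Path(work_dir)
    try:
        out1 = run_pipeline(dict(cfg), out_dir=base / "run1")
        out2 = run_pipeline(dict(cfg), out_dir=base / "run2")
        identical = all((out1 / t).read_bytes() == (out2 / t).read_bytes() for t in tables)
    finally:
        if ctx:
            ctx.cleanup()
    return {"identical": bool(identical), "n_tables": len(tables)}
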