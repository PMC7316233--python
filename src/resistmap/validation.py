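"""Ten-fold out-of-sample validation of the full stack: the level-0 ensemble
AND the level-1 meta-model are refitted for every fold, withheld rows are
predicted, and error metrics, credible-interval coverage and PIT diagnostics
are assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import kstest, norm

from resistmap.datamodel import CovariateStack, PYRETHROIDS
from resistmap.ensemble import DEFAULT_MODEL_SPECS, FeatureBuilder, assign_folds, fit_ensemble
from resistmap.stack import StackPriors, fit_stack
from resistmap.transforms import DEFAULT_N_REF, DEFAULT_SMOOTHING, inverse_transform

COVERAGE_LEVELS = (0.5, 0.8, 0.95)


def rmse_mae(predictions: np.ndarray, observations: np.ndarray) -> tuple[float, float]:
    """Root-mean-square and mean-absolute error of a prediction vector."""
    err = np.asarray(predictions, dtype=float) - np.asarray(observations, dtype=float)
    return float(np.sqrt(np.mean(err**2))), float(np.mean(np.abs(err)))


@dataclass
class ValidationReport:
    """Cross-validated metrics per observation group plus diagnostics."""

    metrics: pd.DataFrame  # rows: group; cols: rmse_natural, mae_natural, rmse_transformed, mae_transformed, n
    coverage: dict[float, float]
    coverage_no_noise: dict[float, float]
    pit_values: np.ndarray
    constituent_rmse: dict[str, float]  # transformed-scale out-of-sample RMSE per level-0 model
    stacked_rmse_transformed: float
    k: int = 10
    seed: int = 0

    def pit_histogram(self, n_bins: int = 10):
        return pit_histogram(self.pit_values, n_bins)

    def to_csv(self, path) -> None:
        self.metrics.to_csv(path, float_format="%.10g")


def _group_of(group_id: str) -> str:
    if group_id.startswith("allele"):
        return "allele"
    insecticide = group_id.split(":")[1]
    return "pyrethroids" if insecticide in PYRETHROIDS else "DDT"


def cross_validate(
    bioassays: Sequence,
    alleles: Sequence,
    covariates: CovariateStack,
    k: int = 10,
    seed: int = 0,
    model_specs=DEFAULT_MODEL_SPECS,
    level0_k: int = 4,
    n_draws: int = 150,
    n_is: int = 60,
    priors: StackPriors | None = None,
    c: float = DEFAULT_SMOOTHING,
    n_ref: int = DEFAULT_N_REF,
) -> ValidationReport:
    """K-fold out-of-sample validation with full refits per fold.

    For each fold the level-0 ensemble is refitted on the training portion
    (with its own internal out-of-fold machinery), the meta-model is refitted
    on the training rows, and the withheld rows are predicted.  Natural-scale
    RMSE/MAE are computed after back-transforming the draw-level linear
    predictor.  Fold seeds are derived from ``seed`` and are independent of
    any stacking-design folds used elsewhere.
    """
    if k < 2:
        raise ValueError("cross-validation needs K >= 2")
    builder = FeatureBuilder(covariates)
    fm = builder.build(bioassays, alleles, c=c)
    n = len(fm)
    folds = assign_folds(n, k, seed)
    meta_group = np.array([_group_of(g) for g in fm.group_ids])
    is_bio = meta_group != "allele"

    pred_mean_t = np.full(n, np.nan)
    pred_var_no_noise = np.full(n, np.nan)
    noise_var = np.full(n, np.nan)
    pit = np.full(n, np.nan)
    pred_mean_nat = np.full(n, np.nan)
    const_sq = {kind: np.full(n, np.nan) for kind, _ in model_specs}

    for f in range(k):
        test = folds == f
        train_fm = fm.subset(~test)
        # Level-0 trains on the combined label (bioassays + allele frequencies).
        ens = fit_ensemble(train_fm, model_specs=model_specs, k=level0_k, seed=seed * 1000 + f)
        m_test_all = ens.predict(fm.x[test])
        test_idx = np.flatnonzero(test)
        for kind_i, (kind, _) in enumerate(model_specs):
            const_sq[kind][test_idx] = (fm.y[test_idx] - m_test_all[:, kind_i]) ** 2
        # One meta-model per insecticide class, fitted to training BIOASSAY rows.
        train_groups = meta_group[~test]
        for gname in ("pyrethroids", "DDT"):
            tr_rows = train_groups == gname
            te_rows = meta_group[test_idx] == gname
            if te_rows.sum() == 0:
                continue
            if tr_rows.sum() < 3:
                continue  # metrics for this group stay undefined (NaN)
            post = fit_stack(
                train_fm.y[tr_rows], ens.oof_matrix[tr_rows], train_fm.node_index[tr_rows],
                covariates.grid, priors=priors, seed=seed * 1000 + f + 1,
                n_draws=n_draws, n_is=n_is,
            )
            rows = test_idx[te_rows]
            m_test = m_test_all[te_rows]
            mu = post.weights @ m_test.T + post.field[:, fm.node_index[rows]]
            pred_mean_t[rows] = mu.mean(axis=0)
            pred_var_no_noise[rows] = mu.var(axis=0)
            noise_var[rows] = np.mean(post.sigma**2)
            pit[rows] = np.mean(norm.cdf(fm.y[rows][None, :], loc=mu, scale=post.sigma[:, None]), axis=0)
            pred_mean_nat[rows] = inverse_transform(mu, c=c, n_ref=n_ref).mean(axis=0)

    rows_out = []
    for grp in ["pyrethroids", "DDT", "allele", "all"]:
        sel = is_bio if grp == "all" else meta_group == grp
        sel = sel & np.isfinite(pred_mean_t)
        if sel.sum() == 0:
            rows_out.append({"group": grp, "n": 0, "rmse_natural": np.nan, "mae_natural": np.nan,
                             "rmse_transformed": np.nan, "mae_transformed": np.nan})
            continue
        rmse_n, mae_n = rmse_mae(pred_mean_nat[sel], fm.proportions[sel])
        rmse_t, mae_t = rmse_mae(pred_mean_t[sel], fm.y[sel])
        rows_out.append({
            "group": grp, "n": int(sel.sum()),
            "rmse_natural": rmse_n, "mae_natural": mae_n,
            "rmse_transformed": rmse_t, "mae_transformed": mae_t,
        })
    metrics = pd.DataFrame(rows_out).set_index("group")

    ok = np.isfinite(pred_mean_t)
    coverage = ci_coverage(pred_mean_t[ok], pred_var_no_noise[ok], noise_var[ok], fm.y[ok], include_noise=True)
    coverage_nn = ci_coverage(pred_mean_t[ok], pred_var_no_noise[ok], noise_var[ok], fm.y[ok], include_noise=False)
    bio_ok = ok  # stack predictions exist only for bioassay rows
    return ValidationReport(
        metrics=metrics,
        coverage=coverage,
        coverage_no_noise=coverage_nn,
        pit_values=pit[bio_ok],
        constituent_rmse={
            kind: float(np.sqrt(np.nanmean(sq[bio_ok]))) for kind, sq in const_sq.items()
        },
        stacked_rmse_transformed=float(np.sqrt(np.mean((pred_mean_t[bio_ok] - fm.y[bio_ok]) ** 2))),
        k=k,
        seed=seed,
    )


def ci_coverage(
    pred_means: np.ndarray,
    pred_vars: np.ndarray,
    noise_vars: np.ndarray,
    observations: np.ndarray,
    include_noise: bool = True,
    levels: Sequence[float] = COVERAGE_LEVELS,
) -> dict[float, float]:
    """Fraction of held-out observations inside each nominal predictive interval.

    ``pred_vars`` is the posterior variance of the latent predictor;
    with ``include_noise`` the measurement-noise variance widens the interval.
    Intervals are central normal intervals.  Zero-width intervals never cover
    (strict inequalities).
    """
    pred_means = np.asarray(pred_means, dtype=float)
    var = np.asarray(pred_vars, dtype=float)
    if include_noise:
        var = var + np.asarray(noise_vars, dtype=float)
    sd = np.sqrt(var)
    y = np.asarray(observations, dtype=float)
    out = {}
    for lv in levels:
        z = norm.ppf(0.5 + lv / 2.0)
        lo = pred_means - z * sd
        hi = pred_means + z * sd
        out[float(lv)] = float(np.mean((y > lo) & (y < hi)))
    return out


def pit_histogram(pit_values: np.ndarray, n_bins: int = 10) -> tuple[np.ndarray, float]:
    """Histogram bin counts of PIT values plus the KS distance from uniform."""
    v = np.asarray(pit_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty PIT input")
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("PIT values must lie in [0, 1]")
    counts, _ = np.histogram(v, bins=n_bins, range=(0.0, 1.0))
    ks = float(kstest(v, "uniform").statistic)
    return counts, ks
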