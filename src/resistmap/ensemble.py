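"""Level-0 ensemble: feature assembly, monthly-covariate principal
components, fold bookkeeping, hyperparameter tuning, out-of-fold prediction
and per-model variable importance.

All insecticide groups and the allele-frequency group are fitted jointly as
a single label vector; group identity enters as a one-hot factor feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from resistmap.datamodel import BioassayObservation, CovariateStack, ObservationGroup, VgscObservation
from resistmap.learners import LEARNER_KINDS, make_learner
from resistmap.transforms import DEFAULT_SMOOTHING, transform_proportion

DEFAULT_MODEL_SPECS: tuple[tuple[str, dict], ...] = (
    ("boosted_trees", {}),
    ("random_forest", {}),
    ("additive_boost", {}),
)


def monthly_to_pcs(monthly: np.ndarray, n_components: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Reduce 12 monthly layers per covariate-year to principal-component scores.

    Parameters
    ----------
    monthly : array, shape (n_years, 12, n_rows, n_cols) for one covariate.
    n_components : number of leading components to keep.

    Returns
    -------
    scores : array, shape (n_components, n_years, n_rows, n_cols); the i-th
        layer holds the (i+1)-th PC score of the pixel's 12-month profile.
    explained : explained-variance fractions, non-increasing.

    The PCA pools pixels across years.  Component signs are fixed so each
    loading vector's largest-magnitude element is positive.
    """
    monthly = np.asarray(monthly, dtype=float)
    if monthly.ndim != 4 or monthly.shape[1] != 12:
        raise ValueError(f"expected (n_years, 12, n_rows, n_cols), got {monthly.shape}")
    ny, _, nr, nc = monthly.shape
    x = monthly.transpose(0, 2, 3, 1).reshape(-1, 12)  # samples x 12 months
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / max(len(xc) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = xc @ evecs[:, :n_components]
    total = evals.sum()
    explained = evals[:n_components] / total if total > 0 else np.zeros(n_components)
    layers = scores.T.reshape(n_components, ny, nr, nc)
    return layers, explained


def assign_folds(n_obs: int, k: int, seed: int) -> np.ndarray:
    """Random K-fold partition; fold sizes differ by at most 1."""
    if k < 2:
        raise ValueError("cross-validation needs K >= 2")
    if k > n_obs:
        raise ValueError(f"K={k} exceeds the number of observations ({n_obs})")
    rng = np.random.default_rng(seed)
    folds = np.empty(n_obs, dtype=int)
    perm = rng.permutation(n_obs)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


class FeatureBuilder:
    """Assembles the model feature matrix for observations and grid pixels.

    Columns: lagged yearly covariates at the observation's pixel-year,
    monthly-covariate principal components, the one-hot observation-group
    factor, and the collection year.  Column order is recorded and stable.
    """

    def __init__(self, covariates: CovariateStack, max_lag: int = 3, n_pcs: int = 3):
        self.grid = covariates.grid
        layers, names = covariates.lagged(max_lag=max_lag)
        if covariates.monthly is not None:
            for i, mname in enumerate(covariates.monthly_names):
                pcs, _ = monthly_to_pcs(covariates.monthly[i], n_components=n_pcs)
                layers = np.concatenate([layers, pcs], axis=0)
                names = names + [f"{mname}{'*' * (j + 1)}" for j in range(n_pcs)]
        self.layers = layers  # (n_layers, n_years, n_rows, n_cols)
        self.layer_names = names
        self.group_categories: list[str] = []

    @property
    def feature_names(self) -> list[str]:
        return self.layer_names + [f"group={g}" for g in self.group_categories] + ["year"]

    def _pixel_features(self, row: int, col: int, t_idx: int) -> np.ndarray:
        return self.layers[:, t_idx, row, col]

    def build(
        self,
        bioassays: Sequence[BioassayObservation],
        alleles: Sequence[VgscObservation] = (),
        c: float = DEFAULT_SMOOTHING,
    ) -> "FeatureMatrix":
        """Feature matrix + transformed label vector for a set of observations."""
        obs: list = list(bioassays) + list(alleles)
        if not obs:
            raise ValueError("no observations")
        groups = [ObservationGroup.of(o).group_id for o in obs]
        self.group_categories = sorted(set(groups))
        rows = []
        node_idx = np.empty(len(obs), dtype=int)
        p = np.empty(len(obs))
        n = np.empty(len(obs))
        for i, o in enumerate(obs):
            r, ccol = self.grid.cell_of(o.lon, o.lat)
            t = self.grid.year_index(o.year)
            node_idx[i] = self.grid.pixel_index(r, ccol) * self.grid.n_years + t
            rows.append(np.concatenate([self._pixel_features(r, ccol, t), self._encode_group(groups[i]), [o.year]]))
            if isinstance(o, BioassayObservation):
                p[i], n[i] = o.mortality, o.n_tested
            else:
                p[i], n[i] = o.frequency, o.n_alleles
        x = np.asarray(rows)
        y = transform_proportion(p, n, c=c)
        kinds = np.array(["bioassay" if isinstance(o, BioassayObservation) else "allele" for o in obs])
        return FeatureMatrix(
            x=x, y=np.asarray(y), names=self.feature_names, node_index=node_idx,
            group_ids=np.array(groups), source_kind=kinds,
            proportions=p, denominators=n,
        )

    def _encode_group(self, group_id: str) -> np.ndarray:
        onehot = np.zeros(len(self.group_categories))
        if group_id in self.group_categories:
            onehot[self.group_categories.index(group_id)] = 1.0
        return onehot

    def grid_features(self, group_id: str, year: int) -> np.ndarray:
        """Feature rows for every grid pixel in one year, group factor forced
        to ``group_id`` — used to build per-insecticide prediction surfaces."""
        t = self.grid.year_index(year)
        n_pix = self.grid.n_pixels
        lay = self.layers[:, t].reshape(len(self.layers), n_pix).T
        onehot = np.tile(self._encode_group(group_id), (n_pix, 1))
        yr = np.full((n_pix, 1), float(year))
        return np.concatenate([lay, onehot, yr], axis=1)


@dataclass
class FeatureMatrix:
    """Feature rows, transformed labels, and bookkeeping for the stack."""

    x: np.ndarray
    y: np.ndarray
    names: list[str]
    node_index: np.ndarray  # pixel * n_years + year index, for field evaluation
    group_ids: np.ndarray
    source_kind: np.ndarray
    proportions: np.ndarray
    denominators: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.x)):
            raise ValueError("feature matrix contains non-finite values")

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            x=self.x[idx], y=self.y[idx], names=self.names, node_index=self.node_index[idx],
            group_ids=self.group_ids[idx], source_kind=self.source_kind[idx],
            proportions=self.proportions[idx], denominators=self.denominators[idx],
        )


def fit_level0(
    x: np.ndarray,
    y: np.ndarray,
    kind: str,
    tuning_grid: Sequence[dict] | None = None,
    k: int = 5,
    seed: int = 0,
):
    """Tune one learner by K-fold out-of-sample RMSE and refit on all rows.

    Returns (fitted model, tuning_report).  ``tuning_grid`` is a sequence of
    hyperparameter dicts; with None or a single entry no tuning loop runs.
    """
    if tuning_grid is not None and len(tuning_grid) == 0:
        raise ValueError("empty tuning grid")
    grid = list(tuning_grid) if tuning_grid else [{}]
    report = {"kind": kind, "k": k, "seed": seed, "candidates": []}
    if len(grid) == 1:
        best_params = grid[0]
        report["candidates"].append({"params": best_params, "rmse": None})
    else:
        folds = assign_folds(len(y), k, seed)
        best_params, best_rmse = None, np.inf
        for params in grid:
            sq = np.empty(len(y))
            for f in range(k):
                test = folds == f
                model = make_learner(kind, params, random_state=seed)
                model.fit(x[~test], y[~test])
                sq[test] = (y[test] - model.predict(x[test])) ** 2
            rmse = float(np.sqrt(sq.mean()))
            report["candidates"].append({"params": params, "rmse": rmse})
            if rmse < best_rmse:
                best_params, best_rmse = params, rmse
    model = make_learner(kind, best_params, random_state=seed)
    model.fit(x, y)
    report["chosen"] = best_params
    return model, report


def oof_predict(
    model_specs: Sequence[tuple[str, dict]],
    x: np.ndarray,
    y: np.ndarray,
    fold_assignment: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold prediction matrix: entry (i, p) is model p's prediction of
    row i from a fit that excluded row i's fold."""
    folds = np.asarray(fold_assignment)
    k = folds.max() + 1
    n = len(y)
    oof = np.full((n, len(model_specs)), np.nan)
    for f in range(k):
        test = folds == f
        train = ~test
        if train.sum() == 0:
            raise ValueError(f"fold {f} leaves no training rows")
        for p, (kind, params) in enumerate(model_specs):
            model = make_learner(kind, params, random_state=seed + p)
            model.fit(x[train], y[train])
            oof[test, p] = model.predict(x[test])
    assert not np.any(np.isnan(oof))
    return oof


def variable_importance(model, kind: str) -> np.ndarray:
    """Normalised per-feature importance of a fitted learner.

    Gain-type for the boosted trees, out-of-bag permutation for the forest,
    cumulative training-error reduction for the additive booster; each
    learner surfaces its own measure through ``feature_importances_``.
    """
    if kind not in LEARNER_KINDS:
        raise ValueError(f"unknown learner kind {kind!r}")
    imp = model.feature_importances_
    if imp is None:
        raise RuntimeError("model is not fitted")
    return np.asarray(imp)


@dataclass
class Level0Ensemble:
    """The fitted constituents plus their prediction matrices and importances."""

    model_specs: list[tuple[str, dict]]
    models: list
    oof_matrix: np.ndarray
    insample_matrix: np.ndarray
    importances: np.ndarray  # (n_models, n_features), rows sum to 1
    fold_assignment: np.ndarray
    tuning_report: list[dict]
    feature_names: list[str] = field(default_factory=list)

    @property
    def model_names(self) -> list[str]:
        return [kind for kind, _ in self.model_specs]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """In-sample-style predictions of all fitted constituents, (n, n_models)."""
        return np.column_stack([m.predict(x) for m in self.models])


def fit_ensemble(
    features: FeatureMatrix,
    model_specs: Sequence[tuple[str, dict]] = DEFAULT_MODEL_SPECS,
    tuning_grids: dict[str, list[dict]] | None = None,
    k: int = 10,
    seed: int = 0,
) -> Level0Ensemble:
    """Fit all constituents: tune + refit on all rows, then produce the
    out-of-fold design matrix from a K-fold partition."""
    x, y = features.x, features.y
    tuned_specs: list[tuple[str, dict]] = []
    models, reports, imps = [], [], []
    for i, (kind, params) in enumerate(model_specs):
        grid = (tuning_grids or {}).get(kind)
        if grid is None:
            grid = [params] if params else None
        model, report = fit_level0(x, y, kind, tuning_grid=grid, k=k, seed=seed + i)
        models.append(model)
        reports.append(report)
        tuned_specs.append((kind, report["chosen"]))
        imps.append(variable_importance(model, kind))
    folds = assign_folds(len(y), k, seed + 1000)
    oof = oof_predict(tuned_specs, x, y, folds, seed=seed)
    insample = np.column_stack([m.predict(x) for m in models])
    return Level0Ensemble(
        model_specs=tuned_specs,
        models=models,
        oof_matrix=oof,
        insample_matrix=insample,
        importances=np.asarray(imps),
        fold_assignment=folds,
        tuning_report=reports,
        feature_names=features.names,
    )
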