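"""The three constituent learners of the level-0 ensemble.

* :class:`DartBoostedTrees` — gradient-boosted regression trees with random
  tree dropout during training and gain-type variable importance.
* :class:`RandomForest` — bagged trees with random feature subsetting and
  out-of-bag permutation importance.
* :class:`ComponentwiseAdditiveBoost` — componentwise L2 boosting of smooth
  univariate base learners, with importance defined as each feature's total
  training-error reduction across the iterations in which it was selected.

All learners expose fit / predict and a ``feature_importances_`` vector of
nonnegative scores summing to 1.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from sklearn.ensemble import BaggingRegressor
from sklearn.tree import DecisionTreeRegressor


class NotFittedError(RuntimeError):
    pass


def _normalize(v: np.ndarray) -> np.ndarray:
    v = np.clip(np.asarray(v, dtype=float), 0.0, None)
    s = v.sum()
    if s <= 0:
        return np.full_like(v, 1.0 / len(v))
    return v / s


class DartBoostedTrees:
    """Gradient boosting with dropout of trees (DART-style regularisation).

    At each iteration every existing tree is independently dropped with
    probability ``dropout_rate``; the new tree fits the residual of the
    remaining ensemble.  With k dropped trees the new tree enters with weight
    lr / (k + 1) and the dropped trees are rescaled by k / (k + 1).
    """

    def __init__(
        self,
        n_estimators: int = 50,
        max_depth: int = 3,
        learning_rate: float = 0.1,
        dropout_rate: float = 0.1,
        min_samples_leaf: int = 3,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.dropout_rate = dropout_rate
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state
        self._trees: list[DecisionTreeRegressor] = []
        self._weights: list[float] = []
        self._intercept = 0.0
        self._fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DartBoostedTrees":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.random_state)
        self._trees, self._weights = [], []
        self._intercept = float(np.mean(y))
        pred = np.full(len(y), self._intercept)
        tree_preds: list[np.ndarray] = []
        for m in range(self.n_estimators):
            if self._trees:
                dropped = rng.random(len(self._trees)) < self.dropout_rate
            else:
                dropped = np.zeros(0, dtype=bool)
            k = int(dropped.sum())
            if k:
                drop_pred = sum(
                    self._weights[j] * tree_preds[j] for j in np.flatnonzero(dropped)
                )
                residual = y - (pred - drop_pred)
            else:
                residual = y - pred
            tree = DecisionTreeRegressor(
                max_depth=self.max_depth,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X, residual)
            new_w = self.learning_rate / (k + 1)
            if k:
                scale = k / (k + 1)
                for j in np.flatnonzero(dropped):
                    pred -= (1 - scale) * self._weights[j] * tree_preds[j]
                    self._weights[j] *= scale
            tp = tree.predict(X)
            pred += new_w * tp
            self._trees.append(tree)
            self._weights.append(new_w)
            tree_preds.append(tp)
        self._fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise NotFittedError("DartBoostedTrees is not fitted")
        X = np.asarray(X, dtype=float)
        out = np.full(X.shape[0], self._intercept)
        for w, t in zip(self._weights, self._trees):
            out += w * t.predict(X)
        return out

    @property
    def feature_importances_(self) -> np.ndarray:
        """Gain importance: impurity reduction summed over trees, weighted by
        each tree's ensemble weight, normalised to sum 1."""
        if not self._fitted:
            raise NotFittedError("DartBoostedTrees is not fitted")
        total = np.zeros(self._trees[0].n_features_in_)
        for w, t in zip(self._weights, self._trees):
            total += abs(w) * t.tree_.compute_feature_importances(normalize=False)
        return _normalize(total)


class RandomForest:
    """Bagged regression trees with random feature subsetting at each split.

    Importance is out-of-bag permutation importance: the mean increase in
    out-of-bag squared error when a feature is permuted, normalised to sum 1.
    Computed during :meth:`fit` (it needs the training data).
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_features: float | str = 0.33,
        min_samples_leaf: int = 3,
        max_depth: int | None = None,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.max_depth = max_depth
        self.random_state = random_state
        self._bag: BaggingRegressor | None = None
        self.feature_importances_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        base = DecisionTreeRegressor(
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            max_depth=self.max_depth,
        )
        self._bag = BaggingRegressor(
            estimator=base,
            n_estimators=self.n_estimators,
            bootstrap=True,
            random_state=self.random_state,
        )
        self._bag.fit(X, y)
        self.feature_importances_ = self._oob_permutation_importance(X, y)
        return self

    def _oob_permutation_importance(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.random_state)
        n, p = X.shape
        deltas = np.zeros(p)
        counts = np.zeros(p)
        for est, samples in zip(self._bag.estimators_, self._bag.estimators_samples_):
            oob = np.setdiff1d(np.arange(n), samples, assume_unique=False)
            if len(oob) < 5:
                continue
            x_oob = X[oob]
            base_err = np.mean((y[oob] - est.predict(x_oob)) ** 2)
            for j in range(p):
                x_perm = x_oob.copy()
                x_perm[:, j] = x_perm[rng.permutation(len(oob)), j]
                err = np.mean((y[oob] - est.predict(x_perm)) ** 2)
                deltas[j] += err - base_err
                counts[j] += 1
        with np.errstate(invalid="ignore"):
            mean_delta = np.where(counts > 0, deltas / np.maximum(counts, 1), 0.0)
        return _normalize(mean_delta)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._bag is None:
            raise NotFittedError("RandomForest is not fitted")
        return self._bag.predict(np.asarray(X, dtype=float))


class _SplineBase:
    """Penalised univariate B-spline base learner (degree 3, ridge penalty)."""

    def __init__(self, x: np.ndarray, n_knots: int = 6, penalty: float = 1.0):
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo < 1e-12:
            hi = lo + 1.0
        inner = np.linspace(lo, hi, n_knots)
        self.knots = np.concatenate([[lo] * 3, inner, [hi] * 3])
        self.n_basis = len(self.knots) - 4
        self.penalty = penalty
        self.lo, self.hi = lo, hi
        b = self.design(x)
        self._solver = np.linalg.inv(b.T @ b + penalty * np.eye(self.n_basis)) @ b.T
        self._design_train = b

    def design(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, self.lo, self.hi)
        return BSpline.design_matrix(xc, self.knots, 3).toarray()

    def solve(self, r: np.ndarray) -> np.ndarray:
        return self._solver @ r

    def fitted(self, coef: np.ndarray) -> np.ndarray:
        return self._design_train @ coef


class _LinearBase:
    """Centred linear base learner for discrete / indicator features."""

    def __init__(self, x: np.ndarray, penalty: float = 1.0):
        self._x = np.column_stack([np.ones_like(x), x])
        self._solver = np.linalg.inv(self._x.T @ self._x + penalty * np.eye(2)) @ self._x.T

    def design(self, x: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones_like(x), x])

    def solve(self, r: np.ndarray) -> np.ndarray:
        return self._solver @ r

    def fitted(self, coef: np.ndarray) -> np.ndarray:
        return self._x @ coef


class ComponentwiseAdditiveBoost:
    """Componentwise L2 boosting over smooth univariate base learners.

    Each iteration fits every candidate base learner (one per feature) to the
    current residual and commits a shrunken copy of the single best one.
    Features with few distinct values get a linear base learner; continuous
    features get a penalised cubic B-spline.
    """

    def __init__(
        self,
        n_iter: int = 100,
        learning_rate: float = 0.1,
        n_knots: int = 6,
        penalty: float = 1.0,
        random_state: int = 0,  # unused; kept for a uniform constructor surface
    ):
        self.n_iter = n_iter
        self.learning_rate = learning_rate
        self.n_knots = n_knots
        self.penalty = penalty
        self.random_state = random_state
        self._fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ComponentwiseAdditiveBoost":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        self._bases = []
        for j in range(p):
            xj = X[:, j]
            if len(np.unique(xj)) <= 4:
                self._bases.append(_LinearBase(xj, penalty=self.penalty))
            else:
                self._bases.append(_SplineBase(xj, n_knots=self.n_knots, penalty=self.penalty))
        self._coefs = [np.zeros(b._solver.shape[0]) for b in self._bases]
        self._intercept = float(np.mean(y))
        self._error_reduction = np.zeros(p)

        resid = y - self._intercept
        for _ in range(self.n_iter):
            best_j, best_red, best_coef, best_fit = -1, -np.inf, None, None
            sse0 = float(resid @ resid)
            for j, base in enumerate(self._bases):
                coef = base.solve(resid)
                fit = base.fitted(coef)
                sse = float(np.sum((resid - fit) ** 2))
                red = sse0 - sse
                if red > best_red:
                    best_j, best_red, best_coef, best_fit = j, red, coef, fit
            if best_j < 0 or best_red <= 0:
                break
            step = self.learning_rate
            self._coefs[best_j] += step * best_coef
            new_resid = resid - step * best_fit
            self._error_reduction[best_j] += sse0 - float(new_resid @ new_resid)
            resid = new_resid
        self._fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise NotFittedError("ComponentwiseAdditiveBoost is not fitted")
        X = np.asarray(X, dtype=float)
        out = np.full(X.shape[0], self._intercept)
        for j, (base, coef) in enumerate(zip(self._bases, self._coefs)):
            if np.any(coef):
                out += base.design(X[:, j]) @ coef
        return out

    @property
    def feature_importances_(self) -> np.ndarray:
        if not self._fitted:
            raise NotFittedError("ComponentwiseAdditiveBoost is not fitted")
        return _normalize(self._error_reduction)


class MeanPredictor:
    """Intercept-only baseline: predicts the training-label mean."""

    def __init__(self, random_state: int = 0):
        self.random_state = random_state
        self._mean: float | None = None
        self._n_features = 0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MeanPredictor":
        self._mean = float(np.mean(y))
        self._n_features = np.asarray(X).shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._mean is None:
            raise NotFittedError("MeanPredictor is not fitted")
        return np.full(np.asarray(X).shape[0], self._mean)

    @property
    def feature_importances_(self) -> np.ndarray:
        if self._mean is None:
            raise NotFittedError("MeanPredictor is not fitted")
        return np.full(self._n_features, 1.0 / max(self._n_features, 1))


LEARNER_KINDS = {
    "boosted_trees": DartBoostedTrees,
    "random_forest": RandomForest,
    "additive_boost": ComponentwiseAdditiveBoost,
    "mean": MeanPredictor,
}


def make_learner(kind: str, params: dict | None = None, random_state: int = 0):
    """Instantiate a learner by kind name with optional hyperparameters."""
    if kind not in LEARNER_KINDS:
        raise ValueError(f"unknown learner kind {kind!r}; expected one of {sorted(LEARNER_KINDS)}")
    params = dict(params or {})
    params.setdefault("random_state", random_state)
    return LEARNER_KINDS[kind](**params)
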