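"""Level-0 ensemble tests: PC reduction, fold bookkeeping, tuning,
out-of-fold prediction (leakage-free by construction) and importances."""

import numpy as np
import pytest
from sklearn.decomposition import PCA

from resistmap.ensemble import (
    FeatureBuilder,
    assign_folds,
    fit_ensemble,
    fit_level0,
    monthly_to_pcs,
    oof_predict,
    variable_importance,
)
from resistmap.learners import (
    ComponentwiseAdditiveBoost,
    DartBoostedTrees,
    MeanPredictor,
    NotFittedError,
    RandomForest,
    make_learner,
)

from conftest import FAST_SPECS


class TestMonthlyToPcs:
    def test_identical_months_degenerate(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((2, 1, 5, 5))
        monthly = np.repeat(base, 12, axis=1)  # every month identical
        layers, explained = monthly_to_pcs(monthly)
        assert explained[0] == pytest.approx(1.0)
        assert np.allclose(layers[1], 0, atol=1e-9)
        assert np.allclose(layers[2], 0, atol=1e-9)

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(1)
        monthly = rng.standard_normal((3, 12, 4, 4))
        _, explained = monthly_to_pcs(monthly)
        assert np.all(np.diff(explained) <= 1e-12)

    def test_matches_independent_pca_oracle(self):
        # 50-pixel toy stack; oracle = scikit-learn PCA (independent code path)
        rng = np.random.default_rng(2)
        monthly = rng.standard_normal((1, 12, 10, 5))
        layers, explained = monthly_to_pcs(monthly)
        x = monthly.transpose(0, 2, 3, 1).reshape(-1, 12)
        pca = PCA(n_components=3).fit(x)
        oracle_scores = pca.transform(x)
        mine = layers.reshape(3, -1).T
        for j in range(3):
            s = np.sign(np.dot(mine[:, j], oracle_scores[:, j]))
            assert np.allclose(mine[:, j], s * oracle_scores[:, j], atol=1e-8)
        assert np.allclose(explained, pca.explained_variance_ratio_, atol=1e-10)

    def test_wrong_month_count_rejected(self):
        with pytest.raises(ValueError):
            monthly_to_pcs(np.zeros((2, 11, 4, 4)))


class TestAssignFolds:
    def test_singleton_folds(self):
        folds = assign_folds(10, 10, seed=0)
        assert sorted(np.bincount(folds)) == [1] * 10

    def test_pigeonhole_sizes(self):
        folds = assign_folds(103, 10, seed=1)
        sizes = np.bincount(folds)
        assert set(sizes) <= {10, 11} and sizes.sum() == 103

    def test_seed_determinism(self):
        assert np.array_equal(assign_folds(50, 5, seed=7), assign_folds(50, 5, seed=7))

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            assign_folds(5, 6, seed=0)

    def test_k_below_two(self):
        with pytest.raises(ValueError):
            assign_folds(10, 1, seed=0)


class TestFitLevel0:
    def test_linear_labels_additive_boost(self):
        rng = np.random.default_rng(3)
        n = 500
        x = rng.standard_normal((n, 4))
        y = 2.0 * x[:, 1]
        model, _ = fit_level0(x[:400], y[:400], "additive_boost",
                              tuning_grid=[{"n_iter": 300, "learning_rate": 0.3}], seed=0)
        rmse = np.sqrt(np.mean((y[400:] - model.predict(x[400:])) ** 2))
        assert rmse < 0.05 * np.std(y)

    @pytest.mark.parametrize("kind", ["boosted_trees", "random_forest", "additive_boost"])
    def test_constant_labels(self, kind):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((60, 3))
        y = np.full(60, 1.7)
        model, _ = fit_level0(x, y, kind, seed=0)
        assert np.allclose(model.predict(x), 1.7, atol=1e-6)

    def test_tuning_selects_by_oos_rmse_and_is_reproducible(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((120, 3))
        y = x[:, 0] + 0.1 * rng.standard_normal(120)
        grid = [{"n_iter": 1}, {"n_iter": 150}]
        _, rep1 = fit_level0(x, y, "additive_boost", tuning_grid=grid, k=4, seed=9)
        _, rep2 = fit_level0(x, y, "additive_boost", tuning_grid=grid, k=4, seed=9)
        assert rep1 == rep2
        assert rep1["chosen"] == {"n_iter": 150}

    def test_empty_tuning_grid(self):
        with pytest.raises(ValueError):
            fit_level0(np.zeros((10, 2)), np.zeros(10), "random_forest", tuning_grid=[])


class TestOofPredict:
    def test_mean_predictor_hand_oracle(self):
        # 6 rows, K=2: row i's entry = mean of the OTHER fold's labels
        y = np.array([1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
        x = np.zeros((6, 1))
        folds = np.array([0, 0, 0, 1, 1, 1])
        oof = oof_predict([("mean", {})], x, y, folds)
        assert np.allclose(oof[:3, 0], 20.0)  # trained on fold 1
        assert np.allclose(oof[3:, 0], 2.0)

    def test_no_leakage_bookkeeping(self):
        # with the mean predictor, a leaked fit would equal the global mean
        y = np.arange(10.0) ** 2  # no 8-row complement mean equals the global mean
        folds = assign_folds(10, 5, seed=0)
        oof = oof_predict([("mean", {})], np.zeros((10, 1)), y, folds)
        for f in range(5):
            expected = y[folds != f].mean()
            assert np.allclose(oof[folds == f, 0], expected)
            assert not np.allclose(expected, y.mean())

    def test_empty_training_fold_rejected(self):
        with pytest.raises(ValueError):
            oof_predict([("mean", {})], np.zeros((3, 1)), np.zeros(3), np.zeros(3, dtype=int))

    def test_oof_rmse_not_better_than_insample(self):
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            x = rng.standard_normal((80, 3))
            y = x[:, 0] + 0.5 * rng.standard_normal(80)
            model = RandomForest(n_estimators=30, random_state=rep).fit(x, y)
            ins_rmse = np.sqrt(np.mean((y - model.predict(x)) ** 2))
            folds = assign_folds(80, 4, seed=rep)
            oof = oof_predict([("random_forest", {"n_estimators": 30})], x, y, folds, seed=rep)
            oof_rmse = np.sqrt(np.mean((y - oof[:, 0]) ** 2))
            if oof_rmse >= ins_rmse:
                wins += 1
        assert wins == 20


class TestVariableImportance:
    def test_single_feature_importance_one(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((100, 1))
        y = x[:, 0]
        for kind in ["boosted_trees", "additive_boost"]:
            model = make_learner(kind, random_state=0).fit(x, y)
            assert variable_importance(model, kind) == pytest.approx([1.0])

    def test_sums_to_one(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((150, 5))
        y = x[:, 0] + 0.3 * rng.standard_normal(150)
        for kind, params in FAST_SPECS:
            model = make_learner(kind, params, random_state=0).fit(x, y)
            imp = variable_importance(model, kind)
            assert imp.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(imp >= 0)

    def test_noise_feature_ranks_below_signal(self):
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            x = rng.standard_normal((120, 2))
            y = 2.0 * x[:, 0] + 0.2 * rng.standard_normal(120)
            model = RandomForest(n_estimators=40, random_state=rep).fit(x, y)
            imp = model.feature_importances_
            if imp[0] > imp[1]:
                wins += 1
        assert wins >= 18

    def test_unfitted_model_raises(self):
        with pytest.raises(NotFittedError):
            DartBoostedTrees().predict(np.zeros((2, 2)))
        with pytest.raises(NotFittedError):
            _ = ComponentwiseAdditiveBoost().feature_importances_
        with pytest.raises(NotFittedError):
            MeanPredictor().predict(np.zeros((2, 2)))


class TestFitEnsemble:
    def test_structure_and_invariants(self, small_dataset):
        bio, allele, cov, *_ = small_dataset
        builder = FeatureBuilder(cov)
        fm = builder.build(bio, allele)
        ens = fit_ensemble(fm, model_specs=FAST_SPECS, k=4, seed=0)
        n = len(fm)
        assert ens.oof_matrix.shape == (n, 3)
        assert ens.insample_matrix.shape == (n, 3)
        assert not np.any(np.isnan(ens.oof_matrix))
        assert np.bincount(ens.fold_assignment).size == 4
        for row in ens.importances:
            assert row.sum() == pytest.approx(1.0, abs=1e-9)

    def test_learners_beat_intercept_baseline(self, small_dataset):
        # each learner's out-of-sample R^2 > 0 on covariate-driven data
        bio, allele, cov, *_ = small_dataset
        builder = FeatureBuilder(cov)
        fm = builder.build(bio, allele)
        folds = assign_folds(len(fm), 4, seed=1)
        specs = FAST_SPECS + [("mean", {})]
        oof = oof_predict(specs, fm.x, fm.y, folds, seed=0)
        base = np.mean((fm.y - oof[:, -1]) ** 2)
        for j in range(3):
            assert np.mean((fm.y - oof[:, j]) ** 2) < base

    def test_feature_names_and_grid_features(self, small_dataset):
        bio, allele, cov, *_ = small_dataset
        builder = FeatureBuilder(cov)
        fm = builder.build(bio, allele)
        assert fm.x.shape[1] == len(fm.names)
        assert "year" in fm.names
        gf = builder.grid_features(fm.group_ids[0], cov.grid.years[0])
        assert gf.shape == (cov.grid.n_pixels, fm.x.shape[1])
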