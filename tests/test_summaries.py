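"""Map-summary tests against brute-force enumeration on printed toy fixtures."""

import numpy as np
import pandas as pd
import pytest

from resistmap.summaries import area_below_threshold, country_trends, interannual_change, weighted_importance


def brute_force_fraction(draws, mask, threshold):
    """Independent oracle: loop over every draw/year/pixel."""
    n_draws, n_years = draws.shape[:2]
    out = np.zeros((n_draws, n_years))
    for d in range(n_draws):
        for t in range(n_years):
            cnt = 0
            tot = 0
            for r in range(draws.shape[2]):
                for c in range(draws.shape[3]):
                    if mask[r, c]:
                        tot += 1
                        if draws[d, t, r, c] < threshold:
                            cnt += 1
            out[d, t] = cnt / tot
    return out


class TestAreaBelowThreshold:
    def test_all_susceptible_zero_proportion(self):
        draws = np.ones((120, 2, 3, 3))
        trend = area_below_threshold(draws, np.ones((3, 3), bool), [2005, 2006])
        assert (trend.table["proportion"] == 0).all()
        assert (trend.table["lower"] == 0).all() and (trend.table["upper"] == 0).all()

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        draws = rng.uniform(size=(150, 2, 4, 4))
        mask = np.ones((4, 4), bool)
        t9 = area_below_threshold(draws, mask, [2005, 2006], threshold=0.9)
        t5 = area_below_threshold(draws, mask, [2005, 2006], threshold=0.5)
        assert (t9.table["proportion"] >= t5.table["proportion"]).all()

    def test_toy_matches_brute_force(self):
        # 3-pixel (1x3), 5-draw printed fixture
        draws = np.array([
            [[[0.50, 0.85, 0.95]]],
            [[[0.50, 0.88, 0.95]]],
            [[[0.50, 0.90, 0.95]]],
            [[[0.50, 0.92, 0.95]]],
            [[[0.50, 0.95, 0.95]]],
        ])  # (5 draws, 1 year, 1 row, 3 cols)
        mask = np.ones((1, 3), bool)
        trend = area_below_threshold(draws, mask, [2010], threshold=0.9)
        oracle = brute_force_fraction(draws, mask, 0.9)
        assert trend.table["lower"].iloc[0] == pytest.approx(np.percentile(oracle[:, 0], 2.5))
        assert trend.table["upper"].iloc[0] == pytest.approx(np.percentile(oracle[:, 0], 97.5))
        mean_surface = draws.mean(axis=0, keepdims=True)
        assert trend.table["proportion"].iloc[0] == pytest.approx(
            brute_force_fraction(mean_surface, mask, 0.9)[0, 0]
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            area_below_threshold(np.ones((5, 1, 2, 2)), np.zeros((2, 2), bool), [2005])

    def test_area_weighting_needs_lats(self):
        with pytest.raises(ValueError):
            area_below_threshold(np.ones((5, 1, 2, 2)), np.ones((2, 2), bool), [2005], area_weighted=True)

    def test_ci_endpoints_bracket_draw_median(self):
        rng = np.random.default_rng(1)
        draws = rng.uniform(size=(200, 1, 5, 5))
        trend = area_below_threshold(draws, np.ones((5, 5), bool), [2005], threshold=0.5)
        frac = brute_force_fraction(draws, np.ones((5, 5), bool), 0.5)
        med = np.median(frac[:, 0])
        assert trend.table["lower"].iloc[0] <= med <= trend.table["upper"].iloc[0]


class TestCountryTrends:
    def test_single_country_equals_region(self):
        rng = np.random.default_rng(2)
        draws = rng.uniform(size=(150, 2, 4, 4))
        mask = np.ones((4, 4), bool)
        reg = area_below_threshold(draws, mask, [2005, 2006])
        ct = country_trends(draws, {"A": mask}, [2005, 2006])
        pd.testing.assert_frame_equal(reg.table, ct["A"].table)

    def test_partition_weighted_mean_identity(self):
        rng = np.random.default_rng(3)
        draws = rng.uniform(size=(100, 1, 4, 4))
        a = np.zeros((4, 4), bool)
        a[:, :1] = True  # 4 pixels
        b = ~a  # 12 pixels
        region = np.ones((4, 4), bool)
        ct = country_trends(draws, {"a": a, "b": b}, [2005])
        reg = area_below_threshold(draws, region, [2005])
        combined = (4 * ct["a"].table["proportion"] + 12 * ct["b"].table["proportion"]) / 16
        assert combined.iloc[0] == pytest.approx(reg.table["proportion"].iloc[0])

    def test_two_country_toy_brute_force(self):
        draws = np.array([
            [[[0.95, 0.50], [0.80, 0.99]]],
            [[[0.10, 0.93], [0.91, 0.89]]],
        ])  # (2 draws, 1 year, 2x2)
        a = np.array([[True, True], [False, False]])
        b = ~a
        ct = country_trends(draws, {"a": a, "b": b}, [2005])
        for name, m in [("a", a), ("b", b)]:
            mean_surface = draws.mean(axis=0, keepdims=True)
            assert ct[name].table["proportion"].iloc[0] == pytest.approx(
                brute_force_fraction(mean_surface, m, 0.9)[0, 0]
            )

    def test_empty_country_skipped_with_warning(self):
        draws = np.ones((5, 1, 2, 2))
        with pytest.warns(UserWarning, match="skipped"):
            out = country_trends(draws, {"empty": np.zeros((2, 2), bool)}, [2005])
        assert out == {}


class TestInterannualChange:
    def test_constant_surface_zero(self):
        s = np.ones((5, 3, 3)) * 0.7
        inc, dec = interannual_change(s)
        assert np.all(inc == 0) and np.all(dec == 0)

    def test_monotone_decline_steps(self):
        # 0.9 -> 0.3 in equal steps of 0.05 (13 years)
        series = np.arange(0.9, 0.3 - 1e-9, -0.05)
        s = series[:, None, None] * np.ones((1, 2, 2))
        inc, dec = interannual_change(s)
        assert np.allclose(dec, 0.05)
        assert np.allclose(inc, 0.0)

    def test_single_pixel_series_brute_force(self):
        series = np.array([0.95, 0.80, 0.85, 0.60, 0.70, 0.20])
        s = series[:, None, None]
        inc, dec = interannual_change(s)
        diffs = [series[i + 1] - series[i] for i in range(5)]
        assert inc[0, 0] == pytest.approx(max(max(diffs), 0.0))
        assert dec[0, 0] == pytest.approx(max(max(-d for d in diffs), 0.0))

    def test_needs_two_years(self):
        with pytest.raises(ValueError):
            interannual_change(np.ones((1, 2, 2)))


class TestWeightedImportance:
    @staticmethod
    def _imp():
        return pd.DataFrame(
            [[0.4, 0.3, 0.2, 0.1],
             [0.1, 0.2, 0.3, 0.4],
             [0.25, 0.25, 0.25, 0.25]],
            index=["m1", "m2", "m3"], columns=["f1", "f2", "f3", "f4"],
        )

    def test_single_model_weight_preserves_ranking(self):
        out = weighted_importance(self._imp(), {"m1": 1.0, "m2": 0.0, "m3": 0.0})
        assert list(out.index) == ["f1", "f2", "f3", "f4"]
        assert np.allclose(out["total"], [0.4, 0.3, 0.2, 0.1])

    def test_equal_weights_identical_vectors_tie(self):
        imp = pd.DataFrame([[0.25] * 4] * 3, index=["m1", "m2", "m3"], columns=list("abcd"))
        out = weighted_importance(imp, {"m1": 1.0, "m2": 1.0, "m3": 1.0})
        assert np.allclose(out["total"], 0.75)

    def test_hand_computed_weighted_sums(self):
        w = {"m1": 0.5, "m2": 0.3, "m3": 0.2}
        out = weighted_importance(self._imp(), w)
        imp = self._imp()
        for f in imp.columns:
            expected = sum(w[m] * imp.loc[m, f] for m in imp.index)
            assert out.loc[f, "total"] == pytest.approx(expected)
        assert out["total"].is_monotonic_decreasing

    def test_mismatched_feature_sets_rejected(self):
        with pytest.raises(ValueError, match="model sets differ"):
            weighted_importance(self._imp(), {"m1": 1.0})

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            weighted_importance(self._imp(), {"m1": -0.1, "m2": 0.5, "m3": 0.5})
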