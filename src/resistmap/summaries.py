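"""Map summary statistics: threshold-area trends with credible intervals,
per-country trends, per-pixel interannual change, and ensemble-weighted
variable importance rankings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ThresholdTrend", "area_below_threshold", "country_trends", "interannual_change", "weighted_importance"]

#: WHO threshold for confirmed phenotypic resistance (proportional mortality).
WHO_RESISTANCE_THRESHOLD = 0.9


@dataclass
class ThresholdTrend:
    """Per-year fraction of in-mask pixels below a mortality threshold."""

    table: pd.DataFrame  # columns: year, proportion, lower, upper
    region_id: str = "region"

    def __post_init__(self) -> None:
        t = self.table
        assert ((t["lower"] <= t["proportion"] + 1e-12) & (t["proportion"] <= t["upper"] + 1e-12)).all()


def _fractions_below(draws: np.ndarray, mask: np.ndarray, threshold: float, weights: np.ndarray | None):
    """Per (draw, year) fraction of in-mask pixels below threshold."""
    sel = draws[:, :, mask]  # (n_draws, n_years, n_in)
    below = sel < threshold
    if weights is None:
        return below.mean(axis=2)
    w = weights[mask]
    return (below * w).sum(axis=2) / w.sum()


def area_below_threshold(
    surface_draws: np.ndarray,
    mask: np.ndarray,
    years: list[int],
    threshold: float = WHO_RESISTANCE_THRESHOLD,
    area_weighted: bool = False,
    lats: np.ndarray | None = None,
    region_id: str = "region",
) -> ThresholdTrend:
    """Proportion of in-mask pixels with mortality below ``threshold`` per year.

    Parameters
    ----------
    surface_draws : array, shape (n_draws, n_years, n_rows, n_cols) of
        draw-level mean-mortality surfaces; the credible interval is the
        2.5/97.5 percentile of the per-draw proportion, so it reflects joint
        spatial uncertainty.  The point estimate uses the posterior mean
        surface.
    mask : boolean (n_rows, n_cols); True = inside the region.
    area_weighted : weight pixels by cos(latitude) instead of counting.
    lats : per-pixel latitudes (n_rows, n_cols); required if area_weighted.
    """
    draws = np.asarray(surface_draws, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty region mask")
    weights = None
    if area_weighted:
        if lats is None:
            raise ValueError("area weighting needs per-pixel latitudes")
        weights = np.cos(np.deg2rad(lats))
    per_draw = _fractions_below(draws, mask, threshold, weights)  # (n_draws, n_years)
    mean_surface = draws.mean(axis=0)[None]
    point = _fractions_below(mean_surface, mask, threshold, weights)[0]
    lower = np.percentile(per_draw, 2.5, axis=0)
    upper = np.percentile(per_draw, 97.5, axis=0)
    table = pd.DataFrame({
        "year": years,
        "proportion": point,
        "lower": np.minimum(lower, point),
        "upper": np.maximum(upper, point),
    })
    return ThresholdTrend(table=table, region_id=region_id)


def country_trends(
    surface_draws: np.ndarray,
    country_masks: dict[str, np.ndarray],
    years: list[int],
    threshold: float = WHO_RESISTANCE_THRESHOLD,
    **kwargs,
) -> dict[str, ThresholdTrend]:
    """Threshold-area trend per country mask; empty countries are skipped."""
    out = {}
    for name, m in country_masks.items():
        m = np.asarray(m, dtype=bool)
        if m.sum() == 0:
            warnings.warn(f"country {name!r} has no unmasked pixels; skipped")
            continue
        out[name] = area_below_threshold(surface_draws, m, years, threshold=threshold, region_id=name, **kwargs)
    return out


def interannual_change(mean_surface: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel maximum interannual increase and decrease of a yearly surface.

    ``mean_surface`` has shape (n_years, n_rows, n_cols) with n_years >= 2.
    Differences are between consecutive years; returns
    (max_increase, max_decrease), both nonnegative per pixel (zero if the
    series only moves the other way).
    """
    s = np.asarray(mean_surface, dtype=float)
    if s.shape[0] < 2:
        raise ValueError("need at least 2 years")
    diffs = np.diff(s, axis=0)
    max_increase = np.maximum(diffs.max(axis=0), 0.0)
    max_decrease = np.maximum((-diffs).max(axis=0), 0.0)
    return max_increase, max_decrease


def weighted_importance(
    importances: pd.DataFrame,
    model_weights: dict[str, float],
    top_n: int | None = None,
) -> pd.DataFrame:
    """Rank features by importance weighted by the meta-model weights.

    Parameters
    ----------
    importances : DataFrame, one row per model (index = model name), one
        column per feature; each row sums to 1.
    model_weights : posterior-mean meta-model weight per model; must cover
        exactly the models in ``importances``.

    Returns a DataFrame indexed by feature with one weighted-importance
    column per model plus ``total``, sorted by descending total.
    """
    models = list(importances.index)
    missing = set(models) ^ set(model_weights)
    if missing:
        raise ValueError(f"model sets differ between importances and weights: {sorted(missing)}")
    if any(w < 0 for w in model_weights.values()):
        raise ValueError("model weights must be >= 0")
    cols = {m: importances.loc[m] * model_weights[m] for m in models}
    out = pd.DataFrame(cols)
    out["total"] = out.sum(axis=1)
    out = out.sort_values("total", ascending=False, kind="stable")
    if top_n is not None:
        out = out.head(top_n)
    return out
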