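"""YAML pipeline configuration: schema validation and parsed accessors.

Configuration is validated eagerly — unknown keys or inconsistent values
raise :class:`ConfigError` before any computation starts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from resistmap.datamodel import DEFAULT_CELL_SIZE, GridDefinition


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


_TOP_KEYS = {
    "seed", "output_dir", "grid", "synthetic", "inputs", "k_folds",
    "level0", "stack", "insecticide_groups", "map_years", "threshold",
    "transforms", "validate", "area_weighted",
}
_GRID_KEYS = {"origin_lon", "origin_lat", "cell_size", "n_cols", "n_rows", "years", "mask_raster"}
_SYNTH_KEYS = {
    "n_covariates", "n_monthly_covariates", "field_sd", "field_range", "temporal_rho",
    "noise_sd", "weight_truth", "covariate_effect", "n_sites", "n_tested_mean",
    "n_tested_shape", "cluster_sd", "n_clusters", "trend", "intercept",
    "vgsc_fraction", "obs_per_site",
}
_INPUT_KEYS = {"bioassay_csv", "allele_csv"}
_STACK_KEYS = {"n_draws", "n_is", "sd_scale", "sigma_scale", "range_mode", "range_log_sd"}
_LEVEL0_KEYS = {"model_specs", "tuning_grids"}
_TRANSFORM_KEYS = {"c", "n_ref"}


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys in {where}: {sorted(unknown)}")


def load_config(source: str | Path | dict) -> dict:
    """Load and validate a pipeline configuration (path, YAML text, or dict)."""
    if isinstance(source, dict):
        cfg = dict(source)
    else:
        path = Path(source)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ConfigError(f"{path}: config must be a mapping")
    _check_keys(cfg, _TOP_KEYS, "top level")
    if "grid" not in cfg:
        raise ConfigError("config needs a 'grid' block")
    _check_keys(cfg["grid"], _GRID_KEYS, "grid")
    if "synthetic" in cfg:
        _check_keys(cfg["synthetic"], _SYNTH_KEYS, "synthetic")
    if "inputs" in cfg:
        _check_keys(cfg["inputs"], _INPUT_KEYS, "inputs")
    if "synthetic" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs either a 'synthetic' or an 'inputs' block")
    if "stack" in cfg:
        _check_keys(cfg["stack"], _STACK_KEYS, "stack")
    if "level0" in cfg:
        _check_keys(cfg["level0"], _LEVEL0_KEYS, "level0")
    if "transforms" in cfg:
        _check_keys(cfg["transforms"], _TRANSFORM_KEYS, "transforms")
    k = int(cfg.get("k_folds", 10))
    if k < 2:
        raise ConfigError("cross-validation needs K >= 2 folds")
    groups = cfg.get("insecticide_groups", ["pyrethroids", "DDT"])
    for g in groups:
        if g not in ("pyrethroids", "DDT"):
            raise ConfigError(f"unknown insecticide group {g!r}")
    return cfg


def grid_from_config(cfg: dict) -> GridDefinition:
    g = cfg["grid"]
    mask = None
    if g.get("mask_raster"):
        from resistmap.io import read_raster

        arr, _ = read_raster(g["mask_raster"])
        mask = np.isfinite(arr) & (arr > 0)
    return GridDefinition(
        origin_lon=float(g["origin_lon"]),
        origin_lat=float(g["origin_lat"]),
        cell_size=float(g.get("cell_size", DEFAULT_CELL_SIZE)),
        n_cols=int(g["n_cols"]),
        n_rows=int(g["n_rows"]),
        years=[int(y) for y in g["years"]],
        mask=mask,
    )
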