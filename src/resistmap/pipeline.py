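"""End-to-end pipeline: transforms -> level-0 ensemble -> GP stacking ->
prediction surfaces -> validation -> map summaries, written to an artifact
directory.  Fully reproducible given fixed seeds: repeated runs produce
byte-identical tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from resistmap.config import ConfigError, grid_from_config, load_config
from resistmap.datamodel import PYRETHROIDS
from resistmap.ensemble import DEFAULT_MODEL_SPECS, FeatureBuilder, fit_ensemble
from resistmap.io import write_observations, write_raster
from resistmap.stack import StackPriors, fit_stack, predict_stack, prediction_draws
from resistmap.summaries import area_below_threshold, interannual_change, weighted_importance
from resistmap.synthetic import SimulationConfig, simulate_covariates, simulate_observations, simulate_true_surface
from resistmap.transforms import DEFAULT_N_REF, DEFAULT_SMOOTHING
from resistmap.validation import cross_validate

_GROUP_INSECTICIDES = {"pyrethroids": list(PYRETHROIDS), "DDT": ["DDT"]}


def _load_data(cfg: dict, grid, seed: int):
    if "synthetic" in cfg:
        s = dict(cfg["synthetic"])
        sim = SimulationConfig(grid=grid, seed=seed, **s)
        cov = simulate_covariates(grid, sim.n_covariates, sim.n_monthly_covariates, seed=seed)
        truth = simulate_true_surface(sim, covariates=cov)
        bio, allele = simulate_observations(truth, sim)
        return bio, allele, cov, truth
    from resistmap.io import read_observations

    inp = cfg["inputs"]
    bio = read_observations(inp["bioassay_csv"], "bioassay")
    allele = read_observations(inp["allele_csv"], "allele") if inp.get("allele_csv") else []
    # Covariates for file-based inputs are simulated surfaces on the grid so
    # the pipeline stays runnable without a raster archive; a real covariate
    # stack can be injected programmatically via run_pipeline(covariates=...).
    cov = simulate_covariates(grid, 5, 0, seed=seed)
    return bio, allele, cov, None


def run_pipeline(config, out_dir: str | Path | None = None, covariates=None) -> Path:
    """Execute the full pipeline described by ``config``.

    Returns the artifact directory.  Artifacts: observation tables, per
    insecticide x year prediction rasters (mean and 95% CI bounds),
    threshold-area trend tables, interannual-change rasters, meta-model
    weight summaries, variable importances, optional cross-validation
    report, and a JSON log of seeds and fitted hyperparameters.
    """
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("output_dir") or "resistmap_output")
    out.mkdir(parents=True, exist_ok=True)

    grid = grid_from_config(cfg)
    tr = cfg.get("transforms", {})
    c = float(tr.get("c", DEFAULT_SMOOTHING))
    n_ref = int(tr.get("n_ref", DEFAULT_N_REF))
    k = int(cfg.get("k_folds", 10))
    threshold = float(cfg.get("threshold", 0.9))
    stack_cfg = cfg.get("stack", {})
    n_draws = int(stack_cfg.get("n_draws", 200))
    n_is = int(stack_cfg.get("n_is", 80))
    priors = StackPriors(
        sd_scale=float(stack_cfg.get("sd_scale", 2.0)),
        sigma_scale=float(stack_cfg.get("sigma_scale", 2.0)),
        range_mode=stack_cfg.get("range_mode"),
        range_log_sd=float(stack_cfg.get("range_log_sd", 1.5)),
    )
    level0_cfg = cfg.get("level0", {})
    model_specs = [
        (spec["kind"], spec.get("params", {})) for spec in level0_cfg.get("model_specs", [])
    ] or list(DEFAULT_MODEL_SPECS)
    log: dict = {"seed": seed, "k_folds": k, "transforms": {"c": c, "n_ref": n_ref}}

    bio, allele, cov, truth = _load_data(cfg, grid, seed)
    if covariates is not None:
        cov = covariates
    write_observations(bio, out / "bioassay_observations.csv")
    if allele:
        write_observations(allele, out / "allele_observations.csv")

    builder = FeatureBuilder(cov)
    fm = builder.build(bio, allele, c=c)
    ens = fit_ensemble(fm, model_specs=model_specs, tuning_grids=level0_cfg.get("tuning_grids"), k=k, seed=seed)
    log["level0"] = {"tuning": ens.tuning_report, "model_names": ens.model_names}

    imp_df = pd.DataFrame(ens.importances, index=ens.model_names, columns=ens.feature_names)
    imp_df.to_csv(out / "level0_importances.csv", float_format="%.10g")
    oof_df = pd.DataFrame(ens.oof_matrix, columns=ens.model_names)
    oof_df.insert(0, "fold", ens.fold_assignment)
    oof_df.to_csv(out / "level0_oof_matrix.csv", index_label="obs", float_format="%.10g")

    groups = cfg.get("insecticide_groups", ["pyrethroids", "DDT"])
    map_years = [int(y) for y in cfg.get("map_years", grid.years)]
    group_ids = np.array([g for g in fm.group_ids])
    summaries_frames = []
    weight_rows = []

    for gname in groups:
        insecticides = _GROUP_INSECTICIDES[gname]
        rows = np.array([g.split(":")[0] == "bioassay" and g.split(":")[1] in insecticides for g in group_ids])
        if rows.sum() < max(10, 2 * k):
            raise ConfigError(f"too few observations ({rows.sum()}) for meta-model group {gname!r}")
        post = fit_stack(
            fm.y[rows], ens.oof_matrix[rows], fm.node_index[rows], grid,
            priors=priors, seed=seed + 17, n_draws=n_draws, n_is=n_is,
        )
        log[f"stack_{gname}"] = post.summary()
        for j, mname in enumerate(ens.model_names):
            weight_rows.append({
                "meta_model": gname, "model": mname,
                "weight_mean": float(np.mean(post.weights[:, j])),
                "weight_q2.5": float(np.percentile(post.weights[:, j], 2.5)),
                "weight_q97.5": float(np.percentile(post.weights[:, j], 97.5)),
            })

        if gname == "pyrethroids":
            w = {m: float(np.mean(post.weights[:, j])) for j, m in enumerate(ens.model_names)}
            ranked = weighted_importance(imp_df, w)
            ranked.to_csv(out / "weighted_importance.csv", float_format="%.10g")

        for insecticide in insecticides:
            gid = f"bioassay:{insecticide}:WHO"
            m_pix = np.vstack([
                ens.predict(builder.grid_features(gid, yr)) for yr in grid.years
            ])  # stacked year-major: rows = year-block of pixels
            # Reorder to node index = pixel * n_years + t.
            m_nodes = np.empty((grid.n_pixels * grid.n_years, len(ens.models)))
            for t in range(grid.n_years):
                block = m_pix[t * grid.n_pixels:(t + 1) * grid.n_pixels]
                m_nodes[t::grid.n_years] = block
            surface = predict_stack(post, m_nodes, grid, years=map_years, c=c, n_ref=n_ref)
            for yi, yr in enumerate(map_years):
                write_raster(surface.mean[yi], grid, out / f"mortality_mean_{insecticide}_{yr}.tif")
                write_raster(surface.lower[yi], grid, out / f"mortality_lower_{insecticide}_{yr}.tif")
                write_raster(surface.upper[yi], grid, out / f"mortality_upper_{insecticide}_{yr}.tif")
            draws = prediction_draws(post, m_nodes, grid, c=c, n_ref=n_ref)
            lats = grid.cell_centers()[1]
            trend = area_below_threshold(
                draws, grid.mask, grid.years, threshold=threshold,
                area_weighted=bool(cfg.get("area_weighted", False)), lats=lats,
                region_id=insecticide,
            )
            tdf = trend.table.copy()
            tdf.insert(0, "insecticide", insecticide)
            summaries_frames.append(tdf)
            mean_over_years = draws.mean(axis=0)
            inc, dec = interannual_change(mean_over_years)
            write_raster(inc, grid, out / f"max_interannual_increase_{insecticide}.tif")
            write_raster(dec, grid, out / f"max_interannual_decrease_{insecticide}.tif")

    pd.DataFrame(weight_rows).to_csv(out / "stack_weights.csv", index=False, float_format="%.10g")
    pd.concat(summaries_frames, ignore_index=True).to_csv(
        out / "threshold_area_trend.csv", index=False, float_format="%.10g"
    )

    if cfg.get("validate", False):
        report = cross_validate(
            bio, allele, cov, k=k, seed=seed + 31, model_specs=model_specs,
            n_draws=max(100, n_draws // 2), n_is=max(40, n_is // 2), c=c, n_ref=n_ref,
        )
        report.to_csv(out / "validation_metrics.csv")
        counts, ks = report.pit_histogram()
        pd.DataFrame({"bin": np.arange(len(counts)), "count": counts}).to_csv(
            out / "pit_histogram.csv", index=False
        )
        log["validation"] = {
            "stacked_rmse_transformed": report.stacked_rmse_transformed,
            "constituent_rmse": report.constituent_rmse,
            "coverage": report.coverage,
            "pit_ks": ks,
        }

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=float)
    return out
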