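"""Synthetic spatiotemporal datasets with the statistical structure the
analysis assumes: smooth gridded covariates, a latent resistance surface
driven by covariate signals plus a separable space-time random field, and
clustered bioassay / allele-frequency sampling with binomial measurement
error.

Everything is driven by a single integer seed and is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from resistmap import gmrf
from resistmap.datamodel import (
    BioassayObservation,
    CovariateStack,
    GridDefinition,
    INSECTICIDES,
    PYRETHROIDS,
    VgscObservation,
)
from resistmap.transforms import DEFAULT_N_REF, DEFAULT_SMOOTHING, inverse_transform


@dataclass
class SimulationConfig:
    """Configuration of the synthetic data generator.

    ``weight_truth`` holds the nonnegative coefficients of the simulated
    covariate-driven signals entering the true surface; ``covariate_effect``
    selects the signal shape applied to each covariate before weighting.
    """

    grid: GridDefinition
    n_covariates: int = 5
    n_monthly_covariates: int = 0
    field_sd: float = 1.0
    field_range: float = 0.5  # degrees
    temporal_rho: float = 0.8
    noise_sd: float = 0.3
    weight_truth: Sequence[float] = (1.0,)
    covariate_effect: str = "linear"  # "linear" | "quadratic"
    n_sites: int = 100
    n_tested_mean: float = 80.0
    n_tested_shape: float = 5.0  # negative-binomial shape; larger = tighter
    cluster_sd: float = 0.15  # degrees; spread of sites around cluster parents
    n_clusters: int = 12
    trend: float = 0.0  # additive per-year drift of the true surface
    intercept: float = 0.0
    vgsc_fraction: float = 0.05  # fraction of sites contributing allele observations
    obs_per_site: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_sd <= 0 or self.field_range <= 0:
            raise ValueError("field_sd and field_range must be > 0")
        if not (-1.0 < self.temporal_rho < 1.0):
            raise ValueError("|temporal_rho| must be < 1")
        if any(w < 0 for w in self.weight_truth):
            raise ValueError("weight_truth entries must be >= 0")


def simulate_covariates(
    grid: GridDefinition,
    n_covariates: int,
    n_monthly: int = 0,
    seed: int = 0,
    range_deg: float = 0.8,
) -> CovariateStack:
    """Generate smooth spatial random surfaces per covariate per year.

    Yearly covariates evolve as an AR(1) over years so lagged copies carry
    signal; monthly covariates add a sinusoidal seasonal cycle on top of the
    yearly surface, 12 layers per year.
    """
    if n_covariates < 1:
        raise ValueError("n_covariates must be >= 1")
    rng = np.random.default_rng(seed)
    nr, nc, ny = grid.n_rows, grid.n_cols, grid.n_years
    range_cells = max(range_deg / grid.cell_size, 1.5)

    fields = gmrf.sample_field(nr, nc, ny, range_cells, 1.0, 0.9, rng, size=n_covariates)
    yearly = fields.reshape(n_covariates, nr, nc, ny).transpose(0, 3, 1, 2).copy()
    names = [f"cov_{i:02d}" for i in range(n_covariates)]

    monthly = None
    mnames: list[str] = []
    if n_monthly > 0:
        base = gmrf.sample_field(nr, nc, ny, range_cells, 1.0, 0.9, rng, size=n_monthly)
        base = base.reshape(n_monthly, nr, nc, ny).transpose(0, 3, 1, 2)
        months = np.arange(12)
        monthly = np.empty((n_monthly, ny, 12, nr, nc))
        for i in range(n_monthly):
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.5, 1.5)
            season = amp * np.sin(2 * np.pi * months / 12.0 + phase)
            noise = 0.1 * rng.standard_normal((ny, 12, nr, nc))
            monthly[i] = base[i][:, None] + season[None, :, None, None] + noise
        mnames = [f"mcov_{i:02d}" for i in range(n_monthly)]

    return CovariateStack(grid=grid, yearly=yearly, yearly_names=names, monthly=monthly, monthly_names=mnames)


def _covariate_signals(cfg: SimulationConfig, cov: CovariateStack) -> np.ndarray:
    """Per-weight signal layers, shape (n_signals, n_years, n_rows, n_cols)."""
    n_sig = len(cfg.weight_truth)
    sig = np.empty((n_sig, cov.grid.n_years, cov.grid.n_rows, cov.grid.n_cols))
    for j in range(n_sig):
        x = cov.yearly[j % cov.n_yearly]
        sig[j] = x if cfg.covariate_effect == "linear" else x + 0.5 * x**2
    return sig


def simulate_true_surface(
    cfg: SimulationConfig, covariates: CovariateStack | None = None
) -> np.ndarray:
    """True transformed resistance surface, shape (n_years, n_rows, n_cols).

    surface = intercept + trend * (year index) + sum_p w_p * signal_p + f,
    with f a separable GMRF (marginal sd ``field_sd``, AR(1) ``temporal_rho``).
    """
    grid = cfg.grid
    rng = np.random.default_rng(cfg.seed + 1)
    if covariates is None:
        covariates = simulate_covariates(grid, cfg.n_covariates, cfg.n_monthly_covariates, seed=cfg.seed)
    range_cells = max(cfg.field_range / grid.cell_size, 1.5)
    f = gmrf.sample_field(
        grid.n_rows, grid.n_cols, grid.n_years, range_cells, cfg.field_sd, cfg.temporal_rho, rng
    )[0]
    f = f.reshape(grid.n_rows, grid.n_cols, grid.n_years).transpose(2, 0, 1)
    surface = cfg.intercept + f
    signals = _covariate_signals(cfg, covariates)
    for w, s in zip(cfg.weight_truth, signals):
        surface = surface + w * s
    if cfg.trend:
        surface = surface + cfg.trend * np.arange(grid.n_years)[:, None, None]
    return surface


def _sample_sites(cfg: SimulationConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Poisson-cluster site process inside the region mask."""
    grid = cfg.grid
    lon0 = grid.origin_lon
    lat0 = grid.origin_lat
    lon1 = lon0 + grid.n_cols * grid.cell_size
    lat1 = lat0 - grid.n_rows * grid.cell_size
    parents = np.column_stack(
        [rng.uniform(lon0, lon1, cfg.n_clusters), rng.uniform(lat1, lat0, cfg.n_clusters)]
    )
    sites: list[tuple[float, float]] = []
    max_tries = cfg.n_sites * 200
    tries = 0
    while len(sites) < cfg.n_sites and tries < max_tries:
        tries += 1
        p = parents[rng.integers(cfg.n_clusters)]
        lon = p[0] + cfg.cluster_sd * rng.standard_normal()
        lat = p[1] + cfg.cluster_sd * rng.standard_normal()
        if grid.contains(lon, lat):
            sites.append((float(lon), float(lat)))
    if len(sites) < cfg.n_sites:
        raise RuntimeError("could not place the requested number of sites inside the mask")
    return sites


def _draw_n_tested(cfg: SimulationConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    """Shifted negative-binomial sample sizes with mean ~ n_tested_mean."""
    shift = 10
    mean = max(cfg.n_tested_mean - shift, 1.0)
    shape = cfg.n_tested_shape
    p = shape / (shape + mean)
    return shift + rng.negative_binomial(shape, p, size=size)


def simulate_observations(
    truth: np.ndarray,
    cfg: SimulationConfig,
    c: float = DEFAULT_SMOOTHING,
    n_ref: int = DEFAULT_N_REF,
) -> tuple[list[BioassayObservation], list[VgscObservation]]:
    """Sample bioassay and allele-frequency tables from a true surface.

    Per observation the transformed truth at the containing pixel-year gets
    Gaussian noise (sd ``noise_sd``), is inverse-transformed to a probability,
    and the recorded mortality is Binomial(n, p) / n.  Allele frequencies use
    a monotone (shifted) map of the same truth.
    """
    grid = cfg.grid
    rng = np.random.default_rng(cfg.seed + 2)
    sites = _sample_sites(cfg, rng)
    years = grid.years
    bio: list[BioassayObservation] = []
    allele: list[VgscObservation] = []
    n_vgsc = int(np.ceil(cfg.vgsc_fraction * len(sites)))
    insecticide_pool = list(PYRETHROIDS) + ["DDT"]

    for s_idx, (lon, lat) in enumerate(sites):
        row, col = grid.cell_of(lon, lat)
        site_id = f"site_{s_idx:04d}"
        obs_years = rng.choice(len(years), size=min(cfg.obs_per_site, len(years)), replace=False)
        for t_idx in sorted(obs_years):
            g = truth[t_idx, row, col]
            n = int(_draw_n_tested(cfg, rng, 1)[0])
            z = g + cfg.noise_sd * rng.standard_normal()
            p = inverse_transform(z, c=c, n_ref=n_ref)
            k = rng.binomial(n, p)
            insecticide = insecticide_pool[int(rng.integers(len(insecticide_pool)))]
            protocol = "WHO" if rng.random() < 0.8 else "CDC"
            bio.append(
                BioassayObservation(
                    site_id=site_id,
                    lon=lon,
                    lat=lat,
                    year=years[t_idx],
                    insecticide=insecticide,
                    protocol=protocol,
                    n_tested=n,
                    mortality=k / n,
                )
            )
        if s_idx < n_vgsc:
            t_idx = int(rng.integers(len(years)))
            g = truth[t_idx, row, col]
            # Resistance-allele frequency rises as mortality falls: monotone
            # decreasing map of the transformed mortality, plus noise.
            z = -g + 0.5 + cfg.noise_sd * rng.standard_normal()
            freq = inverse_transform(z, c=c, n_ref=n_ref)
            n_al = 2 * int(_draw_n_tested(cfg, rng, 1)[0])
            k = rng.binomial(n_al, freq)
            allele.append(
                VgscObservation(
                    site_id=site_id,
                    lon=lon,
                    lat=lat,
                    year=years[t_idx],
                    frequency=k / n_al,
                    n_alleles=n_al,
                )
            )
    return bio, allele
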