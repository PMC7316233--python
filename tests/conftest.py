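"""Shared fixtures: small grids, synthetic datasets and fast learner specs."""

from __future__ import annotations

import numpy as np
import pytest

from resistmap.datamodel import GridDefinition
from resistmap.synthetic import SimulationConfig, simulate_covariates, simulate_observations, simulate_true_surface

# Small hyperparameters so the tree/boosting learners stay fast in tests.
FAST_SPECS = [
    ("boosted_trees", {"n_estimators": 30, "max_depth": 3}),
    ("random_forest", {"n_estimators": 40}),
    ("additive_boost", {"n_iter": 60}),
]


@pytest.fixture
def small_grid() -> GridDefinition:
    return GridDefinition(
        origin_lon=0.0, origin_lat=3.0, cell_size=0.25, n_cols=12, n_rows=12,
        years=[2005, 2006, 2007],
    )


@pytest.fixture
def small_covariates(small_grid):
    return simulate_covariates(small_grid, n_covariates=4, n_monthly=1, seed=11)


@pytest.fixture
def small_dataset(small_grid, small_covariates):
    """(bioassays, alleles, covariates, truth, cfg) on the small grid."""
    cfg = SimulationConfig(
        grid=small_grid, n_covariates=4, field_sd=0.8, field_range=0.8,
        temporal_rho=0.7, noise_sd=0.3, weight_truth=(0.8, 0.5), n_sites=60,
        obs_per_site=2, intercept=1.5, trend=-0.2, vgsc_fraction=0.1, seed=11,
    )
    truth = simulate_true_surface(cfg, covariates=small_covariates)
    bio, allele = simulate_observations(truth, cfg)
    return bio, allele, small_covariates, truth, cfg


def make_grid(n_rows, n_cols, n_years, cell_size=0.25, first_year=2005) -> GridDefinition:
    return GridDefinition(
        origin_lon=0.0, origin_lat=n_rows * cell_size, cell_size=cell_size,
        n_cols=n_cols, n_rows=n_rows, years=list(range(first_year, first_year + n_years)),
    )


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
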