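"""Core data model: observations, observation groups, the prediction grid and
the covariate stack.

Coordinates are geographic decimal degrees.  Grid cells are addressed
row-major from the north-west corner; a pixel value refers to the cell
centre.  Observations are snapped to the containing grid cell for field
evaluation but retain their exact coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Insecticides covered by the susceptibility-test data model.
INSECTICIDES = ("deltamethrin", "permethrin", "lambda_cyhalothrin", "alpha_cypermethrin", "DDT")

#: The four pyrethroids (everything but DDT).
PYRETHROIDS = tuple(i for i in INSECTICIDES if i != "DDT")

#: Supported bioassay protocols.
PROTOCOLS = ("WHO", "CDC")

#: Default cell size: 2.5 arc-minutes in decimal degrees.
DEFAULT_CELL_SIZE = 1.0 / 24.0


class ValidationError(ValueError):
    """An observation record violates a data-model invariant."""


class SchemaError(ValueError):
    """An input table does not match the documented schema."""


@dataclass(frozen=True)
class BioassayObservation:
    """One susceptibility-test result.

    Parameters
    ----------
    site_id : str
        Identifier of the collection site.
    lon, lat : float
        Geographic coordinates in decimal degrees.
    year : int
        Year of sample collection.
    insecticide : str
        One of :data:`INSECTICIDES`.
    protocol : str
        ``"WHO"`` (tube test) or ``"CDC"`` (bottle bioassay).
    n_tested : int
        Number of mosquitoes in the sample (>= 1).
    mortality : float
        Proportional sample mortality in [0, 1].
    """

    site_id: str
    lon: float
    lat: float
    year: int
    insecticide: str
    protocol: str
    n_tested: int
    mortality: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lon) and np.isfinite(self.lat)):
            raise ValidationError(f"non-finite coordinates ({self.lon}, {self.lat})")
        if self.insecticide not in INSECTICIDES:
            raise ValidationError(f"unknown insecticide {self.insecticide!r}")
        if self.protocol not in PROTOCOLS:
            raise ValidationError(f"unknown protocol {self.protocol!r}")
        if self.n_tested < 1:
            raise ValidationError(f"n_tested must be >= 1, got {self.n_tested}")
        if not (0.0 <= self.mortality <= 1.0):
            raise ValidationError(f"mortality {self.mortality} outside [0, 1]")


@dataclass(frozen=True)
class VgscObservation:
    """One target-site allele-frequency record (combined L1014F/L1014S)."""

    site_id: str
    lon: float
    lat: float
    year: int
    frequency: float
    n_alleles: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lon) and np.isfinite(self.lat)):
            raise ValidationError(f"non-finite coordinates ({self.lon}, {self.lat})")
        if self.n_alleles < 1:
            raise ValidationError(f"n_alleles must be >= 1, got {self.n_alleles}")
        if not (0.0 <= self.frequency <= 1.0):
            raise ValidationError(f"frequency {self.frequency} outside [0, 1]")


@dataclass(frozen=True)
class ObservationGroup:
    """Categorical label grouping observations by kind, insecticide and protocol.

    Bioassay observations group by (insecticide, protocol); allele-frequency
    observations form their own single group.
    """

    group_id: str

    @classmethod
    def of(cls, obs: BioassayObservation | VgscObservation) -> "ObservationGroup":
        if isinstance(obs, BioassayObservation):
            return cls(f"bioassay:{obs.insecticide}:{obs.protocol}")
        return cls("allele:vgsc")


@dataclass
class GridDefinition:
    """A regular lat/long prediction grid with a region mask and a year axis.

    ``origin_lon``/``origin_lat`` locate the outer (north-west) corner of the
    grid.  Rows increase southwards, columns eastwards.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_cols: int
    n_rows: int
    years: Sequence[int]
    mask: np.ndarray | None = None  # boolean, shape (n_rows, n_cols); True = inside region

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")
        if self.mask is None:
            self.mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_rows, self.n_cols):
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match grid ({self.n_rows}, {self.n_cols})"
                )
        self.years = [int(y) for y in self.years]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_years(self) -> int:
        return len(self.years)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Return (row, col) of the cell containing a point; raises if outside."""
        col = int(np.floor((lon - self.origin_lon) / self.cell_size))
        row = int(np.floor((self.origin_lat - lat) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) outside the grid")
        return row, col

    def contains(self, lon: float, lat: float) -> bool:
        try:
            r, c = self.cell_of(lon, lat)
        except ValueError:
            return False
        return bool(self.mask[r, c])

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Longitude and latitude of every cell centre, each shape (n_rows, n_cols)."""
        lon = self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lat = self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(lon, lat)

    def pixel_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(int(year))
        except ValueError as exc:
            raise ValueError(f"year {year} not on the grid's year axis") from exc


@dataclass
class CovariateStack:
    """Gridded predictors over space and years.

    ``yearly`` holds covariates on a yearly time step, shape
    ``(n_cov, n_years, n_rows, n_cols)``.  ``monthly`` holds covariates on a
    monthly time step, shape ``(n_monthly, n_years, 12, n_rows, n_cols)``;
    these are reduced to principal-component layers before modelling.
    """

    grid: GridDefinition
    yearly: np.ndarray
    yearly_names: list[str]
    monthly: np.ndarray | None = None
    monthly_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ny, nr, nc = self.grid.n_years, self.grid.n_rows, self.grid.n_cols
        if self.yearly.shape[1:] != (ny, nr, nc):
            raise ValueError(f"yearly covariate shape {self.yearly.shape} does not match grid")
        if self.monthly is not None and self.monthly.shape[1:] != (ny, 12, nr, nc):
            raise ValueError(f"monthly covariate shape {self.monthly.shape} does not match grid")

    @property
    def n_yearly(self) -> int:
        return self.yearly.shape[0]

    @property
    def n_monthly(self) -> int:
        return 0 if self.monthly is None else self.monthly.shape[0]

    def lagged(self, max_lag: int = 3) -> tuple[np.ndarray, list[str]]:
        """Expand yearly covariates with time lags 0..max_lag.

        Lagged values before the first modelled year are clamped to the first
        year.  Returns an array of shape
        ``(n_cov * (max_lag + 1), n_years, n_rows, n_cols)`` and layer names
        with ``(-l)`` suffixes for positive lags.
        """
        layers = []
        names = []
        for i, name in enumerate(self.yearly_names):
            for lag in range(max_lag + 1):
                idx = np.maximum(np.arange(self.grid.n_years) - lag, 0)
                layers.append(self.yearly[i][idx])
                names.append(name if lag == 0 else f"{name}(-{lag})")
        return np.stack(layers), names
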