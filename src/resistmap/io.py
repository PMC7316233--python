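"""Readers and writers for observation tables (CSV) and prediction surfaces
(single-band GeoTIFF).

GeoTIFFs are written with ModelPixelScale / ModelTiepoint tags anchoring the
grid's north-west corner and a GDAL-style no-data tag; masked cells are
stored as NaN.  Round-trips are bit-exact for finite cells.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from resistmap.datamodel import (
    BioassayObservation,
    GridDefinition,
    SchemaError,
    ValidationError,
    VgscObservation,
)

BIOASSAY_COLUMNS = ["site_id", "lon", "lat", "year", "insecticide", "protocol", "n_tested", "mortality"]
ALLELE_COLUMNS = ["site_id", "lon", "lat", "year", "frequency", "n_alleles"]

# TIFF tag codes: GeoTIFF pixel scale / tiepoint, GDAL no-data.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_NODATA = 42113


def read_observations(path: str | Path, schema: str) -> list[BioassayObservation] | list[VgscObservation]:
    """Read and validate an observation table.

    Parameters
    ----------
    path : path to a delimited-text file with the documented header.
    schema : ``"bioassay"`` or ``"allele"``.

    Raises
    ------
    SchemaError if required columns are missing; ValidationError naming the
    offending rows (1-based, excluding the header) if any record violates an
    invariant.
    """
    if schema not in ("bioassay", "allele"):
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = BIOASSAY_COLUMNS if schema == "bioassay" else ALLELE_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    records: list = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            if schema == "bioassay":
                records.append(
                    BioassayObservation(
                        site_id=str(row.site_id),
                        lon=float(row.lon),
                        lat=float(row.lat),
                        year=int(row.year),
                        insecticide=str(row.insecticide),
                        protocol=str(row.protocol),
                        n_tested=int(row.n_tested),
                        mortality=float(row.mortality),
                    )
                )
            else:
                records.append(
                    VgscObservation(
                        site_id=str(row.site_id),
                        lon=float(row.lon),
                        lat=float(row.lat),
                        year=int(row.year),
                        frequency=float(row.frequency),
                        n_alleles=int(row.n_alleles),
                    )
                )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ValidationError(f"{path}: {len(problems)} invalid rows: " + "; ".join(problems))
    return records


def write_observations(
    records: Sequence[BioassayObservation] | Sequence[VgscObservation], path: str | Path
) -> None:
    """Write observation records as CSV with the documented header."""
    path = Path(path)
    if not records:
        raise ValueError("no records to write")
    is_bio = isinstance(records[0], BioassayObservation)
    cols = BIOASSAY_COLUMNS if is_bio else ALLELE_COLUMNS
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in records:
            writer.writerow([repr(getattr(r, c)) if isinstance(getattr(r, c), float) else getattr(r, c) for c in cols])


def write_raster(surface: np.ndarray, grid: GridDefinition, path: str | Path) -> None:
    """Write a per-pixel surface as a georeferenced single-band GeoTIFF.

    Cells outside the grid mask are stored as NaN (declared via the GDAL
    no-data tag).  Values are stored as float64 so finite cells round-trip
    bit-exactly.
    """
    surface = np.asarray(surface, dtype=np.float64)
    if surface.shape != grid.shape:
        raise ValueError(f"surface shape {surface.shape} does not match grid {grid.shape}")
    data = np.where(grid.mask, surface, np.nan)
    cs = float(grid.cell_size)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin_lon), float(grid.origin_lat), 0.0)),
        (_TAG_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(str(path), data, extratags=extratags)


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a single-band GeoTIFF written by :func:`write_raster`.

    Returns the value array (NaN where no-data) and a dict with
    ``origin_lon``, ``origin_lat`` and ``cell_size`` recovered from the
    georeferencing tags (None if absent).
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        geo: dict = {"origin_lon": None, "origin_lat": None, "cell_size": None}
        scale = page.tags.get(_TAG_PIXEL_SCALE)
        tie = page.tags.get(_TAG_TIEPOINT)
        if scale is not None:
            geo["cell_size"] = float(scale.value[0])
        if tie is not None:
            geo["origin_lon"] = float(tie.value[3])
            geo["origin_lat"] = float(tie.value[4])
    return np.asarray(data, dtype=np.float64), geo
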