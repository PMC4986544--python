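"""Plot-table ingestion and point-in-raster spatial joins.

A plot table is a pandas DataFrame carrying, at minimum, columns ``lat``,
``lon`` and ``trees_per_ha`` (stems per hectare, non-negative).  Coordinates
are interpreted in the covariate stack's planar frame — reprojection, where a
real dataset needs it, is a declared pre-step, keeping the join bit-exact.
Joins use the grid's half-open pixel footprints so each point maps to exactly
one pixel.

Records that fall outside the raster extent, hit nodata, or land on an
unlabelled region pixel are never silently dropped: every function returns the
retained table together with a flagged-record report, and
``count(in) == count(retained) + count(flagged)``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grids import CovariateStack, GridSpec
from .synthetic import RegionMap

__all__ = [
    "SchemaError",
    "ValidationError",
    "read_plots",
    "extract_covariates",
    "assign_regions",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("lat", "lon", "trees_per_ha")


class SchemaError(ValueError):
    """The plot file is missing a required column."""


class ValidationError(ValueError):
    """Rows violate the plot schema (non-numeric or negative density)."""


def read_plots(path) -> pd.DataFrame:
    """Read and validate a CSV plot table.

    Requires a header with at least ``lat``, ``lon``, ``trees_per_ha``;
    densities must parse as non-negative numbers and coordinates must be
    finite.  Offending row indices are listed in the raised error.
    """
    plots = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in plots.columns]
    if missing:
        raise SchemaError(f"plot file {path} is missing required column(s): {missing}")
    dens = pd.to_numeric(plots["trees_per_ha"], errors="coerce")
    bad = plots.index[dens.isna() | (dens < 0)].tolist()
    if bad:
        raise ValidationError(
            f"plot file {path}: non-numeric or negative trees_per_ha in rows {bad}"
        )
    coords = plots[["lat", "lon"]].apply(pd.to_numeric, errors="coerce")
    bad = plots.index[~np.isfinite(coords).all(axis=1)].tolist()
    if bad:
        raise ValidationError(f"plot file {path}: non-finite coordinates in rows {bad}")
    plots["trees_per_ha"] = dens
    return plots


def _pixel_index(plots: pd.DataFrame, grid: GridSpec):
    row, col, inside = grid.point_to_pixel(plots["lon"].to_numpy(), plots["lat"].to_numpy())
    return row, col, inside


def extract_covariates(
    plots: pd.DataFrame, stack: CovariateStack
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bind covariate pixel values to coincident plot locations.

    Each in-extent plot receives the band values of the pixel containing it.
    Returns ``(retained, flagged)``: plots outside the raster extent or whose
    pixel is nodata in any band are moved to the flagged report with a
    ``flag_reason`` column and excluded from modelling.
    """
    row, col, inside = _pixel_index(plots, stack.grid)
    out = plots.copy()
    reason = np.where(inside, "", "outside_extent").astype(object)
    r_safe = np.clip(row, 0, stack.grid.n_rows - 1)
    c_safe = np.clip(col, 0, stack.grid.n_cols - 1)
    for name in stack.names:
        vals = stack.band(name)[r_safe, c_safe]
        vals = np.where(inside, vals, np.nan)
        out[name] = vals
        reason[inside & np.isnan(vals)] = "nodata"
    out["flag_reason"] = reason
    retained = out[out["flag_reason"] == ""].drop(columns="flag_reason")
    flagged = out[out["flag_reason"] != ""]
    log.info(
        "extract_covariates: %d in = %d retained + %d flagged",
        len(out), len(retained), len(flagged),
    )
    return retained.copy(), flagged.copy()


def assign_regions(
    plots: pd.DataFrame, regions: RegionMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each plot with the biome and ecoregion of its pixel.

    Plots outside the region rasters or on an unlabelled (nodata) pixel are
    flagged and excluded.  Returns ``(retained, flagged)``.
    """
    row, col, inside = _pixel_index(plots, regions.grid)
    out = plots.copy()
    reason = np.where(inside, "", "outside_extent").astype(object)
    r_safe = np.clip(row, 0, regions.grid.n_rows - 1)
    c_safe = np.clip(col, 0, regions.grid.n_cols - 1)
    biome = regions.biome[r_safe, c_safe].astype(float)
    eco = regions.ecoregion[r_safe, c_safe].astype(float)
    nod = np.isnan(biome) | np.isnan(eco)
    reason[inside & nod] = "region_nodata"
    out["biome_id"] = np.where(inside & ~nod, biome, np.nan)
    out["ecoregion_id"] = np.where(inside & ~nod, eco, np.nan)
    out["flag_reason"] = reason
    retained = out[out["flag_reason"] == ""].drop(columns="flag_reason")
    retained = retained.astype({"biome_id": int, "ecoregion_id": int})
    flagged = out[out["flag_reason"] != ""]
    if len(flagged):
        log.info("assign_regions: flagged %d plot(s): %s",
                 len(flagged), flagged["flag_reason"].value_counts().to_dict())
    return retained.copy(), flagged.copy()
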