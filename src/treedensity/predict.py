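"""Map-algebraic application of regional models with ratio scaling.

Each region's averaged NB model is evaluated pixel-wise over the covariate
stack, then pushed through a fixed four-stage chain:

1. ``raw_per_ha`` — per-pixel expected density ``exp(x' beta)`` in trees/ha;
2. ``truncated`` — outlying predictions capped (default 10,000 trees/ha,
   reflecting the upper range of observed forest structure);
3. ``per_pixel`` — density times pixel area in hectares (the default
   897.27 m pixel covers 0.805 km^2 = 80.5 ha in an equal-area frame);
4. ``forest_scaled`` — ratio estimation against an auxiliary forest-cover
   fraction: each pixel's count is multiplied by ``f_pixel / fbar`` where
   ``fbar`` is the mean forest fraction at the region's reference plots.
   Zero-forest pixels therefore carry zero trees, and two pixels with
   identical covariates differ exactly in proportion to their forest cover.

The stage order is enforced; surfaces only move forward through the chain.
Computation is per-pixel with no cross-pixel dependency, so a tiled run is
bit-identical to a single pass regardless of tile order — the contract that
makes the global computation embarrassingly parallel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grids import CovariateStack, GridSpec
from .models import AveragedModel
from .synthetic import RegionMap

__all__ = [
    "DensitySurface",
    "ScalingConstants",
    "pixel_area",
    "predict_per_ha",
    "truncate",
    "per_pixel_scale",
    "mean_reference_forest",
    "ratio_scale",
    "tile_and_mosaic",
    "apply_scaling_chain",
]

log = logging.getLogger(__name__)

STAGES = ("raw_per_ha", "truncated", "per_pixel", "forest_scaled")


class StageError(RuntimeError):
    """A surface was passed to a step out of pipeline order."""


@dataclass(frozen=True)
class ScalingConstants:
    """Constants of the scaling chain.

    ``cap`` in trees/ha; ``pixel_side_m`` the equal-area pixel side (the
    nominal 1 km^2 global grid measures 897.27 m, i.e. 0.805 km^2 per pixel);
    ``fbar`` maps region id to the mean reference-plot forest fraction.
    """

    cap: float = 10_000.0
    pixel_side_m: float = 897.27
    fbar: dict | None = None

    def __post_init__(self) -> None:
        if not self.cap > 0:
            raise ValueError("cap must be > 0")
        if self.fbar is not None and any(not v > 0 for v in self.fbar.values()):
            raise ValueError("fbar entries must be > 0")

    @property
    def area_ha(self) -> float:
        return pixel_area(self.pixel_side_m)[0]


@dataclass
class DensitySurface:
    """Per-pixel predictions at a known stage of the scaling chain."""

    values: np.ndarray
    grid: GridSpec
    stage: str
    region_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    def _require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise StageError(f"operation requires stage {stage!r}, surface is at {self.stage!r}")


def pixel_area(side_m: float) -> tuple[float, float]:
    """Area of a square pixel: ``(hectares, km^2)``."""
    if not side_m > 0:
        raise ValueError(f"pixel side must be > 0, got {side_m}")
    km2 = (side_m / 1000.0) ** 2
    return 100.0 * km2, km2


def _eta(model: AveragedModel, stack: CovariateStack) -> np.ndarray:
    missing = [t for t in model.terms[1:] if t not in stack.bands]
    if missing:
        raise KeyError(f"model terms missing from stack: {missing}")
    eta = np.full(stack.grid.shape, model.beta[0], dtype=np.float64)
    for b, t in zip(model.beta[1:], model.terms[1:]):
        eta += b * stack.band(t)
    return eta


def predict_per_ha(
    model: AveragedModel, stack: CovariateStack, region_mask: np.ndarray | None = None
) -> DensitySurface:
    """Evaluate ``mu = exp(x' beta)`` per pixel; outside the mask is NaN."""
    mu = np.exp(_eta(model, stack))
    if region_mask is not None:
        mu = np.where(region_mask, mu, np.nan)
    return DensitySurface(values=mu, grid=stack.grid, stage="raw_per_ha")


def truncate(surface: DensitySurface, cap: float = 10_000.0) -> DensitySurface:
    """Cap outlying per-hectare predictions; logs how many pixels were capped."""
    surface._require_stage("raw_per_ha")
    n_capped = int(np.nansum(surface.values > cap))
    if n_capped:
        log.info("truncate: capped %d pixel(s) at %g trees/ha", n_capped, cap)
    return replace(surface, values=np.minimum(surface.values, cap), stage="truncated")


def per_pixel_scale(surface: DensitySurface, area_ha: float) -> DensitySurface:
    """Convert trees/ha to trees per pixel."""
    surface._require_stage("truncated")
    return replace(surface, values=surface.values * area_ha, stage="per_pixel")


def mean_reference_forest(
    plots: pd.DataFrame, forest_cover: np.ndarray, grid: GridSpec, region_col: str = "biome_id"
) -> dict[int, float]:
    """Mean forest fraction at each region's reference-plot pixels."""
    row, col, inside = grid.point_to_pixel(plots["lon"].to_numpy(), plots["lat"].to_numpy())
    if not inside.all():
        raise ValueError("reference plots fall outside the forest-cover raster")
    f = pd.DataFrame({"region": plots[region_col].to_numpy(), "f": forest_cover[row, col]})
    means = f.groupby("region")["f"].mean()
    return {int(rid): float(v) for rid, v in means.items()}


def ratio_scale(
    surface: DensitySurface, forest_cover: np.ndarray, fbar: float | np.ndarray
) -> DensitySurface:
    """Ratio-estimation scaling by auxiliary forest cover.

    ``scaled = value / fbar * f_pixel``; pixels with zero forest cover get
    exactly zero trees.  ``fbar`` may be a scalar or a per-pixel array (the
    region-wise reference mean broadcast onto the grid).
    """
    surface._require_stage("per_pixel")
    fbar_arr = np.asarray(fbar, dtype=float)
    if np.any(fbar_arr <= 0):
        raise ValueError("fbar must be > 0 wherever used")
    scaled = surface.values / fbar_arr * forest_cover
    scaled = np.where(forest_cover == 0, 0.0, scaled)
    return replace(surface, values=scaled, stage="forest_scaled")


def _fbar_raster(fbar: dict, labels: np.ndarray) -> np.ndarray:
    out = np.ones_like(labels, dtype=float)
    for rid, val in fbar.items():
        out[labels == rid] = val
    return out


def apply_scaling_chain(
    raw: DensitySurface,
    scaling: ScalingConstants,
    forest_cover: np.ndarray | None = None,
    fbar: float | np.ndarray | None = None,
) -> DensitySurface:
    """Run truncation, area scaling and (optionally) ratio scaling in order."""
    surf = per_pixel_scale(truncate(raw, scaling.cap), scaling.area_ha)
    if forest_cover is not None:
        if fbar is None:
            raise ValueError("ratio scaling requires fbar")
        surf = ratio_scale(surf, forest_cover, fbar)
    return surf


def _predict_block(
    models: dict, labels: np.ndarray, stack_block: dict[str, np.ndarray], intercept_shape
) -> np.ndarray:
    mu = np.full(labels.shape, np.nan, dtype=np.float64)
    for rid, model in models.items():
        mask = labels == rid
        if not mask.any():
            continue
        eta = np.full(labels.shape, model.beta[0], dtype=np.float64)
        for b, t in zip(model.beta[1:], model.terms[1:]):
            eta += b * stack_block[t]
        mu[mask] = np.exp(eta[mask])
    return mu


def _tiles(grid: GridSpec, tile_size: int):
    for r0 in range(0, grid.n_rows, tile_size):
        for c0 in range(0, grid.n_cols, tile_size):
            yield slice(r0, min(r0 + tile_size, grid.n_rows)), slice(c0, min(c0 + tile_size, grid.n_cols))


def tile_and_mosaic(
    stack: CovariateStack,
    models: dict,
    regions: RegionMap,
    tile_size: int | None = None,
    level: str = "biome",
    tile_order: list[int] | None = None,
) -> DensitySurface:
    """Region-wise per-ha prediction over the grid, tiled and mosaicked.

    Tiles partition the grid without overlap; each tile is evaluated
    independently and written into the mosaic, so the result is bit-identical
    to an untiled pass and independent of tile evaluation order.
    ``tile_size=None`` runs a single pass.
    """
    labels = regions.labels(level)
    missing = sorted(set(np.unique(labels).tolist()) - set(models))
    if missing:
        raise ValueError(f"no model for region(s) {missing}")
    grid = stack.grid
    if tile_size is None:
        tile_size = max(grid.n_rows, grid.n_cols)
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    tiles = list(_tiles(grid, tile_size))
    if tile_order is not None:
        if sorted(tile_order) != list(range(len(tiles))):
            raise ValueError("tile_order must be a permutation of the tile indices")
        tiles = [tiles[i] for i in tile_order]
    mosaic = np.full(grid.shape, np.nan, dtype=np.float64)
    for rs, cs in tiles:
        block = {name: band[rs, cs] for name, band in stack.bands.items()}
        mosaic[rs, cs] = _predict_block(models, labels[rs, cs], block, None)
        log.debug("tile rows %s cols %s: %d pixels", rs, cs, (rs.stop - rs.start) * (cs.stop - cs.start))
    return DensitySurface(values=mosaic, grid=grid, stage="raw_per_ha", region_labels=labels)
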