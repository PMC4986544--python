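"""Synthetic landscapes with known ground truth.

Real forest-inventory plot networks and their covariate stacks cannot be
redistributed, so every downstream stage of the pipeline is exercised on
generated data instead: spatially smooth covariate fields organised in
correlated blocks (to give the variable-clustering stage structure to find),
nested biome/ecoregion partitions, a forest-cover fraction surface, and
negative-binomial plot counts drawn from region-specific log-linear models.
The generative parameters are the ground truth that parameter-recovery and
total-recovery tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .grids import CovariateStack, GridSpec

__all__ = [
    "TrueRegionModel",
    "RegionMap",
    "make_covariate_stack",
    "make_region_map",
    "make_forest_cover",
    "simulate_plots",
    "true_totals",
    "default_true_models",
]


@dataclass(frozen=True)
class TrueRegionModel:
    """Generative log-linear NB model for one region.

    ``beta[0]`` is the intercept on the log-link scale; ``beta[1:]`` pair with
    ``covariate_names``.  ``theta`` is the NB dispersion: counts have mean
    ``mu = exp(x' beta)`` and variance ``mu + mu**2 / theta``.
    """

    region_id: int
    beta: tuple[float, ...]
    theta: float
    covariate_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if len(self.beta) != len(self.covariate_names) + 1:
            raise ValueError(
                f"beta has {len(self.beta)} entries but needs "
                f"{len(self.covariate_names) + 1} (intercept + covariates)"
            )

    def mean_surface(self, stack: CovariateStack) -> np.ndarray:
        """Per-pixel expected density ``exp(x' beta)`` in trees/ha."""
        eta = np.full(stack.grid.shape, self.beta[0], dtype=np.float64)
        for b, name in zip(self.beta[1:], self.covariate_names):
            eta += b * stack.band(name)
        return np.exp(eta)


@dataclass
class RegionMap:
    """Nested biome/ecoregion label rasters on a shared grid.

    Every pixel carries exactly one biome id and one ecoregion id; each
    ecoregion lies within exactly one biome (``ecoregion_to_biome``).
    """

    grid: GridSpec
    biome: np.ndarray
    ecoregion: np.ndarray
    ecoregion_to_biome: dict[int, int] = field(default_factory=dict)

    @property
    def biome_ids(self) -> list[int]:
        return sorted(np.unique(self.biome).tolist())

    @property
    def ecoregion_ids(self) -> list[int]:
        return sorted(np.unique(self.ecoregion).tolist())

    def labels(self, level: str) -> np.ndarray:
        if level == "biome":
            return self.biome
        if level == "ecoregion":
            return self.ecoregion
        raise ValueError(f"level must be 'biome' or 'ecoregion', got {level!r}")


def _smooth_unit_field(shape: tuple[int, int], smoothness: float, rng: np.random.Generator) -> np.ndarray:
    """White noise smoothed to the given length-scale, re-standardised to
    zero mean / unit variance over the grid."""
    z = rng.standard_normal(shape)
    if smoothness > 0:
        z = ndimage.gaussian_filter(z, sigma=smoothness, mode="wrap")
    z = z - z.mean()
    sd = z.std()
    if sd > 0:
        z = z / sd
    return z


def make_covariate_stack(
    grid: GridSpec,
    n_blocks: int = 4,
    vars_per_block: int = 5,
    rho_within: float = 0.8,
    rho_between: float = 0.05,
    smoothness: float = 5.0,
    seed: int = 0,
) -> CovariateStack:
    """Generate spatially smooth covariate bands in correlated blocks.

    Each band mixes a stack-wide latent field (shared by all bands, giving
    between-block correlation ``rho_between``), a block latent field (shared
    within a block, raising within-block correlation to ``rho_within``) and an
    independent residual field.  All three latents are smoothed Gaussian noise
    at the same length-scale, so the bands are spatially coherent while their
    cross-correlations follow the block design.  Bands are standardised to
    zero mean and unit variance over the grid and named
    ``b<block>_v<index>``.
    """
    if n_blocks * vars_per_block < 1:
        raise ValueError("need at least one covariate")
    if not 0 <= rho_between < rho_within <= 1:
        raise ValueError(
            f"require 0 <= rho_between < rho_within <= 1, got {rho_between}/{rho_within}"
        )
    rng = np.random.default_rng(seed)
    a = np.sqrt(rho_between)
    b = np.sqrt(rho_within - rho_between)
    c = np.sqrt(1.0 - rho_within)
    shared = _smooth_unit_field(grid.shape, smoothness, rng)
    bands: dict[str, np.ndarray] = {}
    for blk in range(n_blocks):
        block_latent = _smooth_unit_field(grid.shape, smoothness, rng)
        for j in range(vars_per_block):
            resid = _smooth_unit_field(grid.shape, smoothness, rng)
            f = a * shared + b * block_latent + c * resid
            f = (f - f.mean()) / f.std()
            bands[f"b{blk}_v{j}"] = f
    return CovariateStack(grid=grid, bands=bands)


def make_region_map(
    grid: GridSpec,
    n_biomes: int = 3,
    ecoregions_per_biome: int = 2,
    seed: int = 0,
) -> RegionMap:
    """Partition the grid into contiguous nested regions.

    Biomes are the Voronoi cells of ``n_biomes`` random seed pixels (in pixel
    space); each biome is subdivided into ``ecoregions_per_biome`` Voronoi
    sub-cells of seed pixels drawn inside it.  Ecoregion ids are globally
    unique: ``biome_id * ecoregions_per_biome + j``.
    """
    if n_biomes < 1 or ecoregions_per_biome < 1:
        raise ValueError("need n_biomes >= 1 and ecoregions_per_biome >= 1")
    rng = np.random.default_rng(seed)
    rows, cols = np.indices(grid.shape)
    pts = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)

    def voronoi(points: np.ndarray, n_cells: int) -> np.ndarray:
        idx = rng.choice(len(points), size=min(n_cells, len(points)), replace=False)
        seeds = points[idx]
        d2 = ((points[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    biome = voronoi(pts, n_biomes).reshape(grid.shape)
    ecoregion = np.zeros(grid.shape, dtype=np.uint16)
    eco_to_biome: dict[int, int] = {}
    for b in np.unique(biome):
        mask = biome == b
        sub_pts = pts[mask.ravel()]
        sub = voronoi(sub_pts, ecoregions_per_biome)
        eco_ids = int(b) * ecoregions_per_biome + sub
        ecoregion[mask] = eco_ids
        for j in range(ecoregions_per_biome):
            eco_to_biome[int(b) * ecoregions_per_biome + j] = int(b)
    # ecoregions that received no pixels (tiny biomes) drop out of the map
    present = set(np.unique(ecoregion).tolist())
    eco_to_biome = {e: bb for e, bb in eco_to_biome.items() if e in present}
    return RegionMap(grid=grid, biome=biome.astype(np.uint16), ecoregion=ecoregion, ecoregion_to_biome=eco_to_biome)


def _logit_normal_moments(mu: float, sigma: float) -> tuple[float, float]:
    # Gauss-Hermite quadrature of E[expit(mu + sigma Z)] and the second moment
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    w = weights / weights.sum()
    f = 1.0 / (1.0 + np.exp(-(mu + sigma * nodes)))
    m1 = float(w @ f)
    m2 = float(w @ f**2)
    return m1, float(np.sqrt(max(m2 - m1**2, 0.0)))


def make_forest_cover(
    stack: CovariateStack,
    target_mean: float = 0.63,
    target_sd: float = 0.35,
    corr_with_density: float = 0.5,
    smoothness: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Generate a forest-fraction raster in [0, 1] with prescribed moments.

    The surface is logit-normal: ``f = expit(mu + sigma * z)`` where ``z`` is
    a standardised latent field built as a mixture of the stack's first
    covariate band (weight ``corr_with_density``, so ratio scaling has signal
    correlated with density) and fresh smoothed noise.  ``(mu, sigma)`` are
    solved numerically so the logit-normal mean and s.d. match the targets;
    the defaults reproduce the moderately-forested reference-plot condition
    (mean 0.63, s.d. 0.35).
    """
    if not 0 < target_mean < 1:
        raise ValueError(f"target_mean must lie in (0, 1), got {target_mean}")
    if target_sd < 0:
        raise ValueError(f"target_sd must be >= 0, got {target_sd}")
    if target_sd == 0:
        return np.full(stack.grid.shape, target_mean, dtype=np.float64)
    # a [0,1] variable with mean m cannot exceed the Bernoulli s.d.
    sd_max = np.sqrt(target_mean * (1 - target_mean))
    if target_sd >= 0.98 * sd_max:
        raise ValueError(
            f"target_sd {target_sd} infeasible for mean {target_mean} "
            f"(Bernoulli bound {sd_max:.3f})"
        )
    rng = np.random.default_rng(seed)
    driver = stack.band(stack.names[0])
    noise = _smooth_unit_field(stack.grid.shape, smoothness, rng)
    z = corr_with_density * driver + np.sqrt(1 - corr_with_density**2) * noise
    z = (z - z.mean()) / z.std()

    def resid(p: np.ndarray) -> np.ndarray:
        m, s = _logit_normal_moments(p[0], np.exp(p[1]))
        return np.array([m - target_mean, s - target_sd])

    sol = optimize.root(resid, x0=np.array([np.log(target_mean / (1 - target_mean)), 0.0]))
    if not sol.success:  # pragma: no cover - fsolve fallback
        raise RuntimeError(f"could not match forest-cover moments: {sol.message}")
    mu, sigma = sol.x[0], np.exp(sol.x[1])
    f = 1.0 / (1.0 + np.exp(-(mu + sigma * z)))
    return np.clip(f, 0.0, 1.0)


def simulate_plots(
    stack: CovariateStack,
    regions: RegionMap,
    models: list[TrueRegionModel],
    n_per_region: int = 200,
    level: str = "biome",
    forest_cover: np.ndarray | None = None,
    weight_by_forest: bool = True,
    seed: int = 0,
):
    """Draw NB-distributed plot counts at pixel centres.

    For each region, ``n_per_region`` plot pixels are sampled (with
    replacement, probability proportional to forest fraction when
    ``weight_by_forest`` — field plots sit predominantly in moderately
    forested land) and a count ``y ~ NB(mu, theta)`` with
    ``mu = exp(x' beta)`` is drawn at each.  Returns a plot table with
    columns ``lat, lon, trees_per_ha, biome_id, ecoregion_id`` (planar
    coordinates in the stack's frame; densities are integer trees/ha).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    labels = regions.labels(level)
    by_region = {m.region_id: m for m in models}
    missing = set(np.unique(labels).tolist()) - set(by_region)
    if missing:
        raise ValueError(f"no TrueRegionModel for region(s): {sorted(missing)}")
    if n_per_region < 1:
        raise ValueError("n_per_region must be >= 1")
    cx, cy = stack.grid.pixel_centers()
    rows = []
    for rid in sorted(by_region):
        mask = (labels == rid).ravel()
        if not mask.any():
            continue
        pix = np.flatnonzero(mask)
        if weight_by_forest and forest_cover is not None:
            w = forest_cover.ravel()[pix].astype(float)
            w = w + 1e-9  # keep zero-forest pixels reachable with ~zero weight
            p = w / w.sum()
        else:
            p = None
        chosen = rng.choice(pix, size=n_per_region, replace=True, p=p)
        model = by_region[rid]
        mu_surface = model.mean_surface(stack).ravel()
        mu = mu_surface[chosen]
        y = rng.negative_binomial(model.theta, model.theta / (model.theta + mu))
        r, c = np.unravel_index(chosen, stack.grid.shape)
        eco = regions.ecoregion.ravel()[chosen]
        bio = regions.biome.ravel()[chosen]
        rows.append(
            pd.DataFrame(
                {
                    "lat": cy[r, c],
                    "lon": cx[r, c],
                    "trees_per_ha": y.astype(int),
                    "biome_id": bio.astype(int),
                    "ecoregion_id": eco.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def default_true_models(
    region_ids: list[int],
    covariate_names: list[str],
    seed: int = 0,
    n_signal: int = 2,
    theta_range: tuple[float, float] = (3.0, 8.0),
    mean_density_range: tuple[float, float] = (100.0, 500.0),
    effect_range: tuple[float, float] = (0.2, 0.5),
) -> list[TrueRegionModel]:
    """Draw a plausible generative model per region.

    Each region receives an intercept corresponding to a mean density of
    100-500 trees/ha (the typical range of forested-land plot densities), a
    random pair of signal covariates with log-scale effects of magnitude
    0.2-0.5 and random sign, and a moderate NB dispersion (theta 3-8, i.e.
    clearly overdispersed counts).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    models = []
    for rid in region_ids:
        beta0 = float(np.log(rng.uniform(*mean_density_range)))
        chosen = rng.choice(len(covariate_names), size=min(n_signal, len(covariate_names)), replace=False)
        names = tuple(covariate_names[i] for i in sorted(chosen))
        effects = tuple(
            float(rng.uniform(*effect_range) * rng.choice([-1.0, 1.0])) for _ in names
        )
        models.append(
            TrueRegionModel(
                region_id=int(rid),
                beta=(beta0,) + effects,
                theta=float(rng.uniform(*theta_range)),
                covariate_names=names,
            )
        )
    return models


def true_totals(
    models: list[TrueRegionModel],
    stack: CovariateStack,
    regions: RegionMap,
    forest_cover: np.ndarray | None = None,
    fbar: dict[int, float] | None = None,
    pixel_area_ha: float = 1.0,
    level: str = "biome",
) -> dict[int, float]:
    """Expected per-region tree totals under the generative model.

    ``total_r = sum_pixels area_ha * exp(x' beta_r) * adjustment`` where the
    adjustment is 1 without forest cover, ``f_pixel`` with forest cover, and
    ``f_pixel / fbar_r`` when per-region reference means are supplied —
    mirroring the ratio-estimation step of the prediction pipeline.
    """
    labels = regions.labels(level)
    out: dict[int, float] = {}
    for m in models:
        mask = labels == m.region_id
        if not mask.any():
            continue
        mu = m.mean_surface(stack)[mask]
        adj = 1.0
        if forest_cover is not None:
            adj = forest_cover[mask]
            if fbar is not None:
                adj = adj / fbar[m.region_id]
        out[m.region_id] = float(np.sum(pixel_area_ha * mu * adj, dtype=np.float64))
    return out
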