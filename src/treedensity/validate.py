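"""Cross-validation: holdout regression and bootstrap precision curves.

Two schemes assess the regional models before they are applied spatially:

* **Stratified 80/20 holdout** — within each biome, 20% of plots are
  withheld at random; models fitted on the remainder predict density at the
  withheld plots, and the per-biome predicted means are regressed (OLS)
  against the observed means.  A slope near 1 with a non-significant
  departure indicates unbiased regional means.

* **Bootstrap precision vs sample size** — from a withheld pool, samples of
  size n (default n = 10, 20, ..., 500) are drawn with replacement; each
  replicate records the mean predicted density over its n plots, and the
  curve reports the standard deviation of that mean across replicates (the
  default 10,000 per n).  On an i.i.d. pool the curve follows sigma/sqrt(n),
  so its log-log slope is -1/2; the sample size beyond which further plots
  buy almost no precision (relative gain below 1% per grid step) motivates
  the 50-plot threshold for fitting a region its own model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PrecisionCurve",
    "holdout_split",
    "predicted_vs_observed",
    "bootstrap_precision",
    "bootstrap_sd_curve",
    "fit_loglog",
    "plateau_threshold",
]

log = logging.getLogger(__name__)

DEFAULT_N_GRID = tuple(range(10, 501, 10))


@dataclass
class PrecisionCurve:
    """Bootstrap standard deviation of the mean prediction per sample size."""

    n_grid: tuple[int, ...]
    sd_of_mean: np.ndarray
    reps: int
    seed: int
    statistic: str = "sd_of_replicate_means"

    def __post_init__(self) -> None:
        ns = np.asarray(self.n_grid)
        if not np.all(np.diff(ns) > 0):
            raise ValueError("n_grid must be strictly increasing")
        if np.any(self.sd_of_mean < 0):
            raise ValueError("sd_of_mean must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n_grid, "sd_of_mean": self.sd_of_mean})


def holdout_split(
    plots: pd.DataFrame, frac: float = 0.2, seed: int = 0, stratify: str = "biome_id"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random holdout: withhold ``round(frac * n_b)`` plots per biome.

    Returns ``(train, test)``; the two are disjoint and exhaust the input.
    """
    if not 0 < frac < 1:
        raise ValueError(f"frac must lie in (0, 1), got {frac}")
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    for _, g in plots.groupby(stratify):
        n_test = int(round(frac * len(g)))
        test_idx.append(rng.choice(g.index.to_numpy(), size=n_test, replace=False))
    test_labels = np.concatenate(test_idx) if test_idx else np.array([], dtype=int)
    test_mask = plots.index.isin(test_labels)
    return plots[~test_mask].copy(), plots[test_mask].copy()


def predicted_vs_observed(models: dict, test: pd.DataFrame, stratify: str = "biome_id"):
    """OLS of per-biome predicted mean density on observed mean density.

    Returns ``(slope, intercept, p_slope_eq_1, table)`` where ``p_slope_eq_1``
    is the two-sided t-test p-value for slope = 1 and ``table`` holds the
    per-biome predicted/observed means and standard deviations.
    """
    rows = []
    for rid, g in test.groupby(stratify):
        model = models.get(rid)
        if model is None or len(g) == 0:
            continue
        pred = model.predict_density(g)
        obs = g["trees_per_ha"].to_numpy(dtype=float)
        rows.append(
            {
                "region": rid,
                "n": len(g),
                "pred_mean": pred.mean(),
                "obs_mean": obs.mean(),
                "pred_sd": pred.std(ddof=1) if len(g) > 1 else 0.0,
                "obs_sd": obs.std(ddof=1) if len(g) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError(f"need >= 3 regions with test plots, got {len(table)}")
    x = table["obs_mean"].to_numpy()
    y = table["pred_mean"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate regression: constant means across regions")
    res = stats.linregress(x, y)
    if res.stderr == 0:
        p = 1.0 if np.isclose(res.slope, 1.0) else 0.0
    else:
        t = (res.slope - 1.0) / res.stderr
        p = float(2 * stats.t.sf(abs(t), df=len(table) - 2))
    return float(res.slope), float(res.intercept), p, table


def bootstrap_sd_curve(
    values: np.ndarray,
    n_grid: tuple[int, ...] = DEFAULT_N_GRID,
    reps: int = 10_000,
    seed: int = 0,
    statistic: str = "sd_of_replicate_means",
) -> PrecisionCurve:
    """Bootstrap precision curve over a pool of predicted densities.

    For each n, draw ``reps`` samples of size n with replacement and record
    the mean prediction of each; the curve value at n is the standard
    deviation of those replicate means.  The alternative statistic
    ``"mean_within_sd"`` records instead the mean across replicates of the
    within-sample standard deviation (which estimates the pool sd and is
    nearly flat in n).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty pool")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    sds = np.empty(len(n_grid))
    for i, n in enumerate(n_grid):
        idx = rng.integers(0, values.size, size=(reps, n))
        samples = values[idx]
        if statistic == "sd_of_replicate_means":
            sds[i] = samples.mean(axis=1).std(ddof=1)
        elif statistic == "mean_within_sd":
            sds[i] = samples.std(axis=1, ddof=1).mean()
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    return PrecisionCurve(tuple(n_grid), sds, reps=reps, seed=seed, statistic=statistic)


def bootstrap_precision(
    model,
    withheld_pool: pd.DataFrame,
    n_grid: tuple[int, ...] = DEFAULT_N_GRID,
    reps: int = 10_000,
    seed: int = 0,
    statistic: str = "sd_of_replicate_means",
) -> PrecisionCurve:
    """Precision curve for a fitted model over a withheld plot pool.

    Predictions at the pool plots are computed once; resampling happens on
    the predicted densities.
    """
    if len(withheld_pool) == 0:
        raise ValueError("empty withheld pool")
    pred = model.predict_density(withheld_pool)
    return bootstrap_sd_curve(pred, n_grid=n_grid, reps=reps, seed=seed, statistic=statistic)


def fit_loglog(curve: PrecisionCurve) -> tuple[float, float]:
    """OLS slope and intercept of log(sd) on log(n); requires all sd > 0."""
    if np.any(curve.sd_of_mean <= 0):
        raise ValueError("log-log fit undefined: curve contains sd <= 0")
    res = stats.linregress(np.log(np.asarray(curve.n_grid, dtype=float)), np.log(curve.sd_of_mean))
    return float(res.slope), float(res.intercept)


def plateau_threshold(curve: PrecisionCurve, rel_gain: float = 0.01) -> dict:
    """Smallest n whose relative sd decrease to the next grid point is < rel_gain.

    Returns a dict with the chosen ``n_star``, the criterion and whether the
    curve ever plateaued; a never-plateauing curve returns the largest grid n
    with a warning.
    """
    if len(curve.n_grid) < 3:
        raise ValueError("need at least 3 grid points")
    sd = curve.sd_of_mean
    for i in range(len(sd) - 1):
        if sd[i] == 0:
            return {"n_star": int(curve.n_grid[i]), "rel_gain": rel_gain, "plateaued": True}
        if (sd[i] - sd[i + 1]) / sd[i] < rel_gain:
            return {"n_star": int(curve.n_grid[i]), "rel_gain": rel_gain, "plateaued": True}
    warnings.warn("precision curve never plateaus on the grid; returning max n")
    return {"n_star": int(curve.n_grid[-1]), "rel_gain": rel_gain, "plateaued": False}
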