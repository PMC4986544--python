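"""Summary tables for validation results and regional totals.

Two table shapes are produced, mirroring the way global tree-census results
are conventionally reported:

* a **validation table** — per biome, the count of withheld plots, predicted
  and observed means, standard deviations and sums, with an exact column-sum
  Total row and a percent-difference line comparing predicted and observed
  totals.  By reporting convention, observed per-plot densities (trees/ha)
  are multiplied by 100 to a nominal 100-ha (1 km^2) pixel equivalent so
  they sit on the same scale as per-pixel predictions;

* a **totals table** — per region, plot counts, estimated total trees and
  +/- 2 s.d. margins, with substituted-model rows footnoted as less reliable
  and a Global row whose plot count and tree total are the exact column
  sums.

Numbers are kept at full float64 precision in the returned frames; rounding
happens only at render time.  The published biome-level summary tables from
the global census are bundled as package data so the same aggregation
arithmetic can be exercised on the printed values.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .uncertainty import TotalsReport

__all__ = [
    "percent_difference",
    "validation_table",
    "totals_table",
    "load_published_validation_table",
    "load_published_biome_totals",
]

PIXEL_EQUIVALENT_HA = 100.0  # nominal 1 km^2 pixel in hectares


def percent_difference(pred_sum: float, obs_sum: float) -> float:
    """``100 * (pred - obs) / obs``; rendered to one decimal in tables."""
    if not obs_sum > 0:
        raise ValueError(f"observed sum must be > 0, got {obs_sum}")
    return 100.0 * (pred_sum - obs_sum) / obs_sum


def validation_table(
    models: dict,
    test: pd.DataFrame,
    all_regions: list | None = None,
    stratify: str = "biome_id",
) -> pd.DataFrame:
    """Validation summary per biome with exact column-sum Total row.

    ``pred`` columns use the model's per-plot density predictions scaled to
    the nominal 100-ha pixel; ``obs`` columns use observed density x 100.
    Regions listed in ``all_regions`` but absent from the test set appear as
    em-dash rows.
    """
    rows = []
    present = []
    for rid, g in test.groupby(stratify):
        model = models.get(rid)
        if model is None:
            continue
        pred = model.predict_density(g) * PIXEL_EQUIVALENT_HA
        obs = g["trees_per_ha"].to_numpy(dtype=float) * PIXEL_EQUIVALENT_HA
        present.append(rid)
        rows.append(
            {
                "region": rid,
                "n_withheld": len(g),
                "pred_mean": pred.mean(),
                "obs_mean": obs.mean(),
                "sd": pred.std(ddof=1) if len(g) > 1 else 0.0,
                "pred_sum": pred.sum(),
                "obs_sum": obs.sum(),
                "sd_sum": pred.std(ddof=1) * len(g) if len(g) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    for rid in all_regions or []:
        if rid not in present:
            table.loc[len(table)] = {"region": rid} | {c: np.nan for c in table.columns if c != "region"}
    table = table.sort_values("region", key=lambda s: s.astype(str)).reset_index(drop=True)
    total = {
        "region": "Total",
        "n_withheld": table["n_withheld"].sum(),
        "pred_mean": table["pred_mean"].sum(),
        "obs_mean": table["obs_mean"].sum(),
        "sd": np.nan,
        "pred_sum": table["pred_sum"].sum(),
        "obs_sum": table["obs_sum"].sum(),
        "sd_sum": np.nan,
    }
    table.loc[len(table)] = total
    table.attrs["percent_difference"] = round(
        percent_difference(total["pred_sum"], total["obs_sum"]), 1
    )
    return table


def totals_table(report: TotalsReport, scale: float = 1.0) -> pd.DataFrame:
    """Totals per region plus an exact-sum Global row.

    ``scale`` divides tree counts for readability (e.g. 1e9 to report in
    billions, the convention for global totals).  Substituted-model regions
    carry ``substituted=True`` and should be treated as less reliable.
    """
    table = report.per_region.copy()
    table["total_trees"] = table["total_trees"] / scale
    table["margin"] = table["margin"] / scale
    table = table.drop(columns="sd")
    table.loc[len(table)] = {
        "region": "Global",
        "n_plots": int(table["n_plots"].sum()),
        "total_trees": table["total_trees"].sum(),
        "margin": report.global_margin / scale,
        "substituted": False,
    }
    return table


def _published(name: str) -> pd.DataFrame:
    with resources.files("treedensity.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_published_validation_table() -> pd.DataFrame:
    """Published biome-level holdout validation summary (printed values).

    Biomes whose models were borrowed from an analog have no withheld plots
    and appear as all-NaN rows, as in the published table.
    """
    return _published("biome_validation_summary.csv")


def load_published_biome_totals() -> pd.DataFrame:
    """Published per-biome tree totals with +/- 2 s.d. margins in billions."""
    return _published("biome_totals.csv")
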