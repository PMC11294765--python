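"""Regional travel-time summaries: weighted median, IQR, maximum, mean.

Travel times are summarised *for women of reproductive age*, i.e. each
cell's time is weighted by the demand living there (population weighting,
the default); unweighted cell statistics are retained for comparison.

The quantile convention is the lower step function of the weighted CDF:
sort cells by time and return the smallest time whose cumulative
normalised weight reaches the requested probability.  With equal weights
this reduces to the lower empirical quantile, and it is exactly
reproducible by replicating each cell ``weight`` times — the oracle the
tests use.  Cells with infinite time (no capable facility anywhere) are
excluded from the quantiles; their weighted share is reported separately
as ``unreachable_pct``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .demand import UNASSIGNED
from .grids import Raster

__all__ = ["weighted_quantile", "summarize"]

NATIONAL_ID = "ALL"


def weighted_quantile(values, weights, q: float) -> float:
    """Lower weighted quantile: smallest value with cumulative weight >= q."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have the same shape")
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("all weights are zero")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order]) / total
    pos = int(np.searchsorted(cum, q, side="left"))
    pos = min(pos, len(values) - 1)
    return float(values[order][pos])


def _stats_block(times: np.ndarray, weights: np.ndarray) -> dict[str, float]:
    finite = np.isfinite(times)
    w_total = weights.sum()
    out: dict[str, float] = {}
    if w_total > 0:
        out["unreachable_pct"] = 100.0 * float(weights[~finite].sum()) / float(w_total)
    else:
        out["unreachable_pct"] = float("nan")
    t, w = times[finite], weights[finite]
    if len(t) == 0 or w.sum() <= 0:
        # nothing reachable carries weight: flag, do not propagate NaN maths
        out.update(
            median_h=float("nan"), q1_h=float("nan"), q3_h=float("nan"),
            max_h=float("nan"), mean_h=float("nan"), unreachable=True,
        )
        return out
    out["median_h"] = weighted_quantile(t, w, 0.5)
    out["q1_h"] = weighted_quantile(t, w, 0.25)
    out["q3_h"] = weighted_quantile(t, w, 0.75)
    out["max_h"] = float(t.max())
    out["mean_h"] = float(np.average(t, weights=w))
    out["unreachable"] = False
    return out


def summarize(
    surface: Raster,
    demand: Raster,
    assignment: np.ndarray,
    region_order: list[str],
    service: str,
    weighting: str = "population",
    national_id: str = NATIONAL_ID,
) -> pd.DataFrame:
    """Per-region and national travel-time statistics for one service.

    Returns one row per region (sorted id order) plus a pooled national row
    (region id ``ALL``) with columns region, service, median_h, q1_h, q3_h,
    max_h, mean_h, unreachable_pct.  ``weighting="population"`` weights each
    cell by demand; ``"unweighted"`` weights every in-study cell equally.
    """
    if weighting not in {"population", "unweighted"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    if not surface.grid.compatible_with(demand.grid):
        raise ValueError("surface and demand grids are not aligned")
    if assignment.shape != surface.grid.shape:
        raise ValueError("assignment shape does not match the grid")

    times = surface.values
    if weighting == "population":
        weights = np.where(demand.valid, demand.values, 0.0)
    else:
        weights = np.ones(surface.grid.shape)

    rows = []
    in_study = (assignment != UNASSIGNED) & ~np.isnan(times)
    for idx, rid in enumerate(region_order):
        sel = (assignment == idx) & ~np.isnan(times)
        if not sel.any():
            continue
        rows.append(
            {"region": rid, "service": service, **_stats_block(times[sel], weights[sel])}
        )
    rows.append(
        {
            "region": national_id,
            "service": service,
            **_stats_block(times[in_study], weights[in_study]),
        }
    )
    return pd.DataFrame(rows)
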