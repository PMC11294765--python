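"""Overlay of the three timely-access masks into 8 access-zone types.

The truth table over (ANC, ID, PNC) timely access defines the multilevel
health care access zones:

    ====  ===  ==  ===  ==========================================
    type  ANC  ID  PNC  description
    ====  ===  ==  ===  ==========================================
    1      T   T   T    timely access to full CMPHS
    2      T   T   F    timely ANC and ID
    3      T   F   T    timely ANC and PNC
    4      F   T   T    timely ID and PNC
    5      T   F   F    timely ANC only
    6      F   T   F    timely ID only
    7      F   F   T    timely PNC only
    8      F   F   F    no timely access to any package
    ====  ===  ==  ===  ==========================================

Zone shares report, per type, the percentage of study-area land and of the
demand population (women of reproductive age) falling in that type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import round_half_up
from .grids import GridSpec, Raster

__all__ = [
    "ZONE_TYPES",
    "ZONE_DESCRIPTIONS",
    "classify_zones",
    "cell_areas_km2",
    "zone_shares",
    "rounded_zone_shares",
]

ZONE_TYPES = (1, 2, 3, 4, 5, 6, 7, 8)

ZONE_DESCRIPTIONS = {
    1: "Able to obtain timely CMPHS (ANC, ID, and PNC)",
    2: "Able to obtain timely ANC and ID",
    3: "Able to obtain timely ANC and PNC",
    4: "Able to obtain timely ID and PNC",
    5: "Able to obtain timely ANC",
    6: "Able to obtain timely ID",
    7: "Able to obtain timely PNC",
    8: "Not able to obtain timely CMPHS",
}

# lookup by bit pattern 4*ANC + 2*ID + PNC
_CODE_LUT = np.array([8, 7, 6, 4, 5, 3, 2, 1], dtype=np.int16)

#: zone types whose cells have timely access to each package
MERGED_TYPES = {"ANC": (1, 2, 3, 5), "ID": (1, 2, 4, 6), "PNC": (1, 3, 4, 7)}


def classify_zones(
    mask_anc: np.ndarray,
    mask_id: np.ndarray,
    mask_pnc: np.ndarray,
    study_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Combine three boolean masks into the 1..8 zone-type raster.

    ``study_mask`` restricts the study area; cells outside it get code 0
    (nodata).  The mapping is a bijection on the 2^3 mask combinations.
    """
    masks = [np.asarray(m, dtype=bool) for m in (mask_anc, mask_id, mask_pnc)]
    if not (masks[0].shape == masks[1].shape == masks[2].shape):
        raise ValueError("coverage masks must share one grid shape")
    bits = 4 * masks[0].astype(np.int16) + 2 * masks[1] + masks[2]
    zones = _CODE_LUT[bits]
    if study_mask is not None:
        if study_mask.shape != zones.shape:
            raise ValueError("study_mask shape does not match the masks")
        zones = np.where(study_mask, zones, 0).astype(np.int16)
    return zones


def cell_areas_km2(grid: GridSpec, mode: str = "uniform") -> np.ndarray:
    """Per-cell area weights.

    ``uniform`` gives every cell weight 1 (count-based shares, the
    default); ``cosine`` scales geographic cells by the cosine of their
    centroid latitude, the first-order correction for lon/lat cells
    shrinking away from the equator.
    """
    if mode == "uniform":
        return np.ones(grid.shape)
    if mode == "cosine":
        _, yy = grid.cell_centers()
        return np.cos(np.radians(yy))
    raise ValueError(f"unknown area mode {mode!r}")


def zone_shares(
    zones: np.ndarray,
    demand: Raster,
    cell_area: np.ndarray | str = "uniform",
) -> pd.DataFrame:
    """Percent of land area and of demand population per zone type.

    ``cell_area`` is either a per-cell weight array or an area mode name
    passed to :func:`cell_areas_km2`.  Zero-demand cells count toward area
    but not population.  Percentages are rounded half-up to 2 decimals at
    report time; each column of unrounded shares sums to exactly 100.
    """
    if zones.shape != demand.grid.shape:
        raise ValueError("zone raster and demand raster grids are not aligned")
    if isinstance(cell_area, str):
        cell_area = cell_areas_km2(demand.grid, mode=cell_area)
    in_study = zones > 0
    area = np.where(in_study, cell_area, 0.0)
    pop = np.where(in_study & demand.valid, demand.values, 0.0)
    total_area = float(area.sum())
    total_pop = float(pop.sum())
    if total_area <= 0:
        raise ValueError("study area has zero total area")
    if total_pop <= 0:
        raise ValueError("study area has zero total population")
    rows = []
    for t in ZONE_TYPES:
        sel = zones == t
        rows.append(
            {
                "type": t,
                "description": ZONE_DESCRIPTIONS[t],
                "area_pct": 100.0 * float(area[sel].sum()) / total_area,
                "pop_pct": 100.0 * float(pop[sel].sum()) / total_pop,
            }
        )
    return pd.DataFrame(rows)


def rounded_zone_shares(shares: pd.DataFrame) -> pd.DataFrame:
    """Report form of :func:`zone_shares`: percentages at 2 decimals."""
    out = shares.copy()
    out["area_pct"] = out["area_pct"].map(lambda v: round_half_up(v, 2))
    out["pop_pct"] = out["pop_pct"].map(lambda v: round_half_up(v, 2))
    return out
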