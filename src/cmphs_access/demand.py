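"""Dasymetric redistribution of a gridded density to announced region totals.

A density raster G (here: WorldPop-style pregnancy density at roughly 1 km
resolution) fixes the *shape* of the demand distribution, while per-region
totals T_j of women of reproductive age fix its *mass*.  Each cell i in
region j receives

    P_ij = T_j * G_ij / G_j,     G_j = sum of G over region j,

so per-region sums of P reproduce T_j exactly and the within-region pattern
of G is preserved (scale-invariant in G, monotone in G within a region).
"""

from __future__ import annotations

import logging

import numpy as np
import shapely

from .grids import Raster, RegionSet

__all__ = ["assign_cells_to_regions", "redistribute"]

logger = logging.getLogger(__name__)

#: assignment code for cells whose centroid lies in no region
UNASSIGNED = -1


def assign_cells_to_regions(
    raster: Raster, regions: RegionSet
) -> tuple[np.ndarray, list[str]]:
    """Assign each non-nodata cell to the region containing its centroid.

    Returns ``(assignment, region_order)`` where ``assignment`` is an int
    array of the raster's shape holding indices into ``region_order``
    (regions in sorted-id order), or :data:`UNASSIGNED`.  A centroid lying
    exactly on a shared boundary goes to the region with the
    lexicographically smallest id, which makes the assignment deterministic.
    Nodata cells and centroids outside every polygon stay unassigned.
    """
    if raster.grid.crs != regions.crs:
        raise ValueError(
            f"CRS mismatch: raster {raster.grid.crs!r} vs regions {regions.crs!r}"
        )
    xx, yy = raster.grid.cell_centers()
    assignment = np.full(raster.grid.shape, UNASSIGNED, dtype=int)
    order = regions.sorted_ids()
    candidates = raster.valid
    for idx, rid in enumerate(order):
        open_cells = candidates & (assignment == UNASSIGNED)
        if not open_cells.any():
            break
        geom = regions.geometries[rid]
        shapely.prepare(geom)
        hit = shapely.intersects_xy(geom, xx[open_cells], yy[open_cells])
        rows, cols = np.nonzero(open_cells)
        assignment[rows[hit], cols[hit]] = idx
    n_out = int((candidates & (assignment == UNASSIGNED)).sum())
    if n_out:
        logger.info("%d cell(s) outside all regions left unassigned", n_out)
    return assignment, order


def redistribute(
    raster: Raster,
    regions: RegionSet,
    assignment: np.ndarray | None = None,
    region_order: list[str] | None = None,
) -> Raster:
    """Rescale the density raster so per-region sums equal the region totals.

    If ``assignment`` is omitted it is computed via
    :func:`assign_cells_to_regions`.  Nodata and unassigned cells receive no
    demand.  A region with a positive total but zero density mass is an
    error (there is no shape to scale); a region with a zero total and
    positive mass is zeroed with a warning.
    """
    if assignment is None:
        assignment, region_order = assign_cells_to_regions(raster, regions)
    if region_order is None:
        region_order = regions.sorted_ids()
    if assignment.shape != raster.grid.shape:
        raise ValueError("assignment shape does not match raster")

    g = np.where(raster.valid, raster.values, 0.0)
    if (g < 0).any():
        raise ValueError("density raster contains negative values")
    out = np.where(raster.valid, 0.0, np.nan)
    for idx, rid in enumerate(region_order):
        mask = assignment == idx
        g_j = float(g[mask].sum())
        t_j = float(regions.totals.get(rid, 0.0))
        if t_j > 0 and g_j == 0:
            raise ValueError(
                f"region {rid!r} has total {t_j} but zero density mass to rescale"
            )
        if t_j == 0:
            if g_j > 0:
                logger.warning("region %r has zero total; demand zeroed", rid)
            continue
        out[mask] = g[mask] * (t_j / g_j)
    return raster.copy_with(out)
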