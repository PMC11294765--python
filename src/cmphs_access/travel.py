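"""Nearest-neighbour travel-time surfaces.

For every grid cell the shortest travel time to a facility capable of a
given service package is the straight-line distance to the nearest capable
facility divided by a constant walking speed (default 4 km/h).  Distances
are haversine great-circle kilometres on a spherical Earth (R = 6371 km)
for lon/lat inputs, or planar Euclidean for projected/analytic inputs.  A
cell is *timely covered* when its time is at or below the threshold
(default 2 h, closed inequality).

Large facility sets are accelerated with a k-d tree (3-D chord embedding on
the sphere, plain 2-D in planar mode); the correctness contract is the
exhaustive all-pairs minimum, which the tests enforce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grids import GridSpec, Raster

__all__ = [
    "TravelParams",
    "great_circle_km",
    "nearest_time_surface",
    "coverage_mask",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: facility counts up to this size use the exhaustive all-pairs path
_BRUTE_FORCE_MAX = 64

#: relative slack for detecting distance ties when resolving nearest ids
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class TravelParams:
    """Travel model: walking speed, timeliness threshold, distance metric."""

    speed_kmh: float = 4.0
    threshold_h: float = 2.0
    earth_radius_km: float = EARTH_RADIUS_KM
    distance_mode: str = "haversine"

    def __post_init__(self) -> None:
        if self.speed_kmh <= 0:
            raise ValueError("speed must be > 0")
        if self.threshold_h <= 0:
            raise ValueError("threshold must be > 0")
        if self.distance_mode not in {"haversine", "planar"}:
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")


def great_circle_km(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_KM):
    """Haversine great-circle distance in km between two lon/lat points.

    Vectorised over any broadcastable combination of inputs.  The arcsine
    argument is clamped to [0, 1] so antipodal rounding cannot produce NaN.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    return 2.0 * radius * np.arcsin(np.sqrt(h))


def _embed_sphere(lon, lat, radius: float) -> np.ndarray:
    """Lon/lat degrees -> 3-D Cartesian points on a sphere of given radius."""
    lam, phi = np.radians(lon), np.radians(lat)
    return np.column_stack(
        (radius * np.cos(phi) * np.cos(lam),
         radius * np.cos(phi) * np.sin(lam),
         radius * np.sin(phi))
    )


def _pairwise_km(
    cx: np.ndarray, cy: np.ndarray, fx: np.ndarray, fy: np.ndarray,
    params: TravelParams,
) -> np.ndarray:
    """Distance matrix (n_cells, n_fac) under the configured metric."""
    if params.distance_mode == "planar":
        return np.hypot(cx[:, None] - fx[None, :], cy[:, None] - fy[None, :])
    return great_circle_km(
        cy[:, None], cx[:, None], fy[None, :], fx[None, :],
        radius=params.earth_radius_km,
    )


def nearest_time_surface(
    grid: GridSpec,
    facilities: pd.DataFrame,
    capability: pd.DataFrame,
    service: str,
    params: TravelParams = TravelParams(),
    return_nearest: bool = False,
):
    """Per-cell hours to the nearest facility capable of ``service``.

    Returns a :class:`Raster` of hours (+inf everywhere when no facility is
    capable, with a warning), and optionally an object array of the nearest
    capable facility id per cell.  Distance ties are broken toward the
    lexicographically smallest facility id so output is deterministic.
    """
    if len(facilities) == 0:
        raise ValueError("facility table is empty")
    if service not in {"ANC", "ID", "PNC"}:
        raise ValueError(f"unknown service {service!r}")
    cap = facilities[["facility_id", "lon", "lat"]].merge(
        capability[["facility_id", service]], on="facility_id"
    )
    cap = cap[cap[service].astype(bool)].sort_values("facility_id")
    nearest = np.full(grid.shape, None, dtype=object)
    if cap.empty:
        logger.warning("no facility capable of %s; surface is all-infinite", service)
        surface = Raster(grid=grid, values=np.full(grid.shape, np.inf))
        return (surface, nearest) if return_nearest else surface

    fx = cap["lon"].to_numpy(float)
    fy = cap["lat"].to_numpy(float)
    fids = cap["facility_id"].to_numpy(object)
    xx, yy = grid.cell_centers()
    cx, cy = xx.ravel(), yy.ravel()

    if len(cap) <= _BRUTE_FORCE_MAX:
        dmat = _pairwise_km(cx, cy, fx, fy, params)
        # argmin on id-sorted facilities returns the smallest id among ties
        idx = dmat.argmin(axis=1)
    else:
        idx = _tree_nearest(cx, cy, fx, fy, params)
    # always evaluate the final distance with the exact metric, so the tree
    # path agrees bit-for-bit with the exhaustive all-pairs minimum
    if params.distance_mode == "planar":
        dist = np.hypot(cx - fx[idx], cy - fy[idx])
    else:
        dist = great_circle_km(cy, cx, fy[idx], fx[idx],
                               radius=params.earth_radius_km)

    hours = (dist / params.speed_kmh).reshape(grid.shape)
    nearest[...] = fids[idx].reshape(grid.shape)
    surface = Raster(grid=grid, values=hours)
    return (surface, nearest) if return_nearest else surface


def _tree_nearest(cx, cy, fx, fy, params: TravelParams) -> np.ndarray:
    """Nearest-facility index per cell via k-d tree, deterministic on ties."""
    if params.distance_mode == "planar":
        fac_pts = np.column_stack((fx, fy))
        cell_pts = np.column_stack((cx, cy))
    else:
        fac_pts = _embed_sphere(fx, fy, params.earth_radius_km)
        cell_pts = _embed_sphere(cx, cy, params.earth_radius_km)
    tree = cKDTree(fac_pts)
    k = min(2, len(fx))
    d, i = tree.query(cell_pts, k=k)
    if k == 1:
        d, i = d[:, None], i[:, None]
    idx = i[:, 0].copy()
    if k == 2:
        # near-ties: re-resolve against every equally-near facility so the
        # smallest facility id wins (facilities are pre-sorted by id)
        tied = d[:, 1] - d[:, 0] <= _TIE_RTOL * np.maximum(d[:, 0], 1.0)
        for row in np.nonzero(tied)[0]:
            ball = tree.query_ball_point(
                cell_pts[row], d[row, 0] * (1 + _TIE_RTOL) + 1e-12
            )
            idx[row] = min(ball)
    return idx


def coverage_mask(surface: Raster, params: TravelParams = TravelParams()) -> np.ndarray:
    """Boolean timely-access mask: time <= threshold; infinite is never covered."""
    with np.errstate(invalid="ignore"):
        return np.asarray(surface.values <= params.threshold_h) & np.isfinite(
            surface.values
        )
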