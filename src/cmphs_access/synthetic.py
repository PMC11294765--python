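"""Synthetic scenario generator with known ground truth.

Real inputs for this kind of analysis — a national SARA-style facility
census, a WorldPop-style pregnancy-density raster, yearbook totals of women
of reproductive age per province — are rarely redistributable, so every
pipeline stage here is exercised on generated scenarios that emulate their
statistical shape:

* a rectangular study window tiled into regions (provinces), each with a
  log-uniform total of women of reproductive age;
* a density raster mixing isotropic Gaussian urban clusters with a sparse
  uniform rural background;
* a facility network sampled proportional to density (facilities co-locate
  with people), with three levels and per-indicator Bernoulli readiness
  flags whose default prevalences equal the observed national facility
  census rates (e.g. 0.9131 for IPTp in pregnancy, 0.3268 for emergency
  obstetric care);
* analytic "known truth" scenarios (planar geometry) whose coverage sets
  are discs computable in closed form.

A single integer seed drives everything through fixed per-stage
substreams, so adding a stage never perturbs the draws of earlier ones and
regeneration is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .catalog import IndicatorCatalog, default_catalog
from .grids import WGS84, GridSpec, Raster, RegionSet
from .travel import TravelParams

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "generate_regions",
    "generate_density",
    "generate_facilities",
    "generate_scenario",
    "known_truth_scenario",
]

KM_PER_DEGREE = 111.195  # 2*pi*6371/360

# stage codes for seed substreams; frozen so streams stay independent
_STAGE_REGIONS = 101
_STAGE_DENSITY = 102
_STAGE_FACILITIES = 103
_STAGE_FLAGS = 104

#: default per-indicator readiness prevalence (national census rates)
DEFAULT_PREVALENCE = {
    "Iron supplementation": 0.6939,
    "Folic acid supplementation": 0.6712,
    "Tetanus toxoid vaccination": 0.8846,
    "Monitoring for hypertensive disorder of pregnancy": 0.7769,
    "IPTp for malaria": 0.9131,
    "HIV counseling and testing for HIV-positive pregnant women": 0.8878,
    "Antiviral treatment for HIV-positive pregnant women": 0.8735,
    "Monitoring of labor with partograph": 0.8256,
    "Parenteral administration of oxytocin": 0.8061,
    "Assisted vaginal delivery": 0.7296,
    "Manual removal of placenta": 0.7153,
    "Antibiotics for preterm": 0.5506,
    "Blank partograph": 0.7808,
    "Parenteral administration of magnesium sulfate": 0.6997,
    "Emergency obstetric care": 0.3268,
    "Immediate and exclusive breastfeeding": 0.8515,
    "Thermal protection": 0.8385,
    "Hygenic cord care": 0.8476,
    "Neonatal resuscitation": 0.7276,
    "Kangaroo mother care": 0.7095,
    "Injectable antibiotics for neonatal sepsis": 0.4968,
    "HIV counseling and testing for infants born to HIV-positive women": 0.8761,
    "ARV prophylaxis to newborns of HIV-positive pregnant women": 0.8722,
    "HIV-positive infant and young child feeding counseling": 0.8865,
    "BCG vaccine": 0.5746,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic world; defaults emulate a down-scaled province
    network on a ~110 km square window at ~1 km resolution."""

    seed: int = 0
    n_regions: int = 4
    nrows: int = 100
    ncols: int = 100
    cellsize: float = 0.01  # degrees, ~1.1 km
    xmin: float = 34.0
    ymin: float = -20.0
    crs: str = WGS84
    clusters_per_region: int = 2
    cluster_spread_km: float = 5.0
    background_fraction: float = 0.1
    facilities_per_level: dict[str, int] = field(
        default_factory=lambda: {"primary": 60, "secondary": 4, "tertiary": 1}
    )
    indicator_prevalence: dict[str, float] | None = None
    total_range: tuple[float, float] = (5e4, 5e5)
    capability_mode: str = "from_flags"
    forced_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.nrows <= 0 or self.ncols <= 0 or self.cellsize <= 0:
            raise ValueError("study window must be positive")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")
        if self.capability_mode not in {"from_flags", "forced"}:
            raise ValueError(f"unknown capability_mode {self.capability_mode!r}")
        for name, p in (self.indicator_prevalence or {}).items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {name!r} outside [0, 1]")
        if any(v < 0 for v in self.facilities_per_level.values()):
            raise ValueError("facility counts must be >= 0")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            nrows=self.nrows, ncols=self.ncols,
            xmin=self.xmin, ymin=self.ymin,
            cellsize=self.cellsize, crs=self.crs,
        )

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])


@dataclass
class Scenario:
    """A complete generated world plus the catalog it was built against."""

    config: ScenarioConfig
    regions: RegionSet
    density: Raster
    facilities: pd.DataFrame
    catalog: IndicatorCatalog


def generate_regions(config: ScenarioConfig) -> RegionSet:
    """Tile the study window into ``n_regions`` rectangles with WRA totals.

    Rows of nearly equal height are filled left to right; totals are drawn
    log-uniform in ``config.total_range``, mimicking the spread of
    provincial yearbook counts.
    """
    g = config.grid
    n = config.n_regions
    per_row = int(np.ceil(np.sqrt(n)))
    full_rows, rem = divmod(n, per_row)
    counts = [per_row] * full_rows + ([rem] if rem else [])
    height = (g.ymax - g.ymin) / len(counts)

    rng = config.rng(_STAGE_REGIONS)
    ids, geoms, names, totals = [], {}, {}, {}
    k = 0
    for r, cnt in enumerate(counts):
        width = (g.xmax - g.xmin) / cnt
        y0 = g.ymax - (r + 1) * height
        for c in range(cnt):
            k += 1
            rid = f"R{k:02d}"
            x0 = g.xmin + c * width
            ids.append(rid)
            geoms[rid] = box(x0, y0, x0 + width, y0 + height)
            names[rid] = f"Region {k:02d}"
    lo, hi = config.total_range
    draw = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    for rid, t in zip(ids, draw):
        totals[rid] = float(np.round(t))
    return RegionSet(region_ids=ids, geometries=geoms, totals=totals,
                     names=names, crs=config.crs)


def _km_offsets(xx, yy, cx, cy, crs: str):
    """Approximate km offsets of grid centers from a point, per CRS."""
    if crs == WGS84:
        dx = (xx - cx) * KM_PER_DEGREE * np.cos(np.radians(yy))
        dy = (yy - cy) * KM_PER_DEGREE
    else:  # planar: coordinates already km
        dx, dy = xx - cx, yy - cy
    return dx, dy


def generate_density(config: ScenarioConfig, regions: RegionSet) -> Raster:
    """Per-region mixture of Gaussian urban bumps over a uniform background.

    Cluster centers are drawn at cell centroids (weighted uniformly within
    the region), so with zero background the densest cell is exactly a
    cluster center.  Values are non-negative everywhere.
    """
    g = config.grid
    xx, yy = g.cell_centers()
    rng = config.rng(_STAGE_DENSITY)
    values = np.zeros(g.shape)
    bg = config.background_fraction
    from .demand import assign_cells_to_regions  # local import avoids a cycle

    assignment, order = assign_cells_to_regions(Raster(g, values), regions)
    for idx, _rid in enumerate(order):
        mask = assignment == idx
        if not mask.any():
            continue
        bump = np.zeros(g.shape)
        if config.clusters_per_region > 0 and bg < 1.0:
            rows, cols = np.nonzero(mask)
            pick = rng.choice(len(rows), size=config.clusters_per_region,
                              replace=len(rows) < config.clusters_per_region)
            for p in pick:
                cx, cy = xx[rows[p], cols[p]], yy[rows[p], cols[p]]
                dx, dy = _km_offsets(xx, yy, cx, cy, config.crs)
                d2 = dx * dx + dy * dy
                bump += np.exp(-0.5 * d2 / config.cluster_spread_km**2)
        values[mask] = bg + (1.0 - bg) * bump[mask]
    return Raster(grid=g, values=values)


def generate_facilities(
    config: ScenarioConfig,
    regions: RegionSet,
    density: Raster,
    catalog: IndicatorCatalog | None = None,
) -> pd.DataFrame:
    """Sample a facility network with density-proportional locations.

    Facility cells are drawn proportional to the density raster (urban
    concentration), positions jittered uniformly within the cell.  Flags
    are independent Bernoulli draws per indicator at the configured
    prevalence; in ``forced`` mode a ``forced_fraction`` share of the
    facilities instead receives every flag (fully package-capable), the
    rest none — convenient for overlay tests with controlled supply.
    """
    catalog = catalog or default_catalog()
    g = config.grid
    weights = np.where(density.valid, density.values, 0.0).ravel()
    if weights.sum() <= 0:
        raise ValueError("density raster has zero total mass")
    weights = weights / weights.sum()
    xx, yy = g.cell_centers()

    n_total = sum(config.facilities_per_level.values())
    rng = config.rng(_STAGE_FACILITIES)
    cells = rng.choice(weights.size, size=n_total, p=weights)
    jx = rng.uniform(-0.5, 0.5, size=n_total) * g.cellsize
    jy = rng.uniform(-0.5, 0.5, size=n_total) * g.cellsize
    lon = xx.ravel()[cells] + jx
    lat = yy.ravel()[cells] + jy

    levels: list[str] = []
    for level in ("tertiary", "secondary", "primary"):
        levels += [level] * config.facilities_per_level.get(level, 0)

    table = pd.DataFrame(
        {
            "facility_id": [f"F{i:04d}" for i in range(n_total)],
            "lon": lon,
            "lat": lat,
            "level": levels,
        }
    )

    flag_rng = config.rng(_STAGE_FLAGS)
    prevalence = dict(DEFAULT_PREVALENCE)
    prevalence.update(config.indicator_prevalence or {})
    if config.capability_mode == "forced":
        n_forced = int(round(config.forced_fraction * n_total))
        forced = np.zeros(n_total, dtype=bool)
        forced[flag_rng.choice(n_total, size=n_forced, replace=False)] = True
        for name in catalog.indicators():
            table[name] = forced
    else:
        for name in catalog.indicators():
            p = prevalence.get(name, 0.5)
            table[name] = flag_rng.random(n_total) < p
    return table


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate regions, density, and facilities in one deterministic pass."""
    catalog = default_catalog()
    regions = generate_regions(config)
    density = generate_density(config, regions)
    facilities = generate_facilities(config, regions, density, catalog)
    return Scenario(config=config, regions=regions, density=density,
                    facilities=facilities, catalog=catalog)


# ---------------------------------------------------------------------------
# analytic known-truth scenarios (planar geometry: closed-form discs)
# ---------------------------------------------------------------------------

def _planar_world(nrows: int, ncols: int, total: float):
    """Uniform-demand planar world: 1 km cells, one region, crs 'local-km'."""
    g = GridSpec(nrows=nrows, ncols=ncols, xmin=0.0, ymin=0.0,
                 cellsize=1.0, crs="local-km")
    regions = RegionSet(
        region_ids=["R01"],
        geometries={"R01": box(g.xmin, g.ymin, g.xmax, g.ymax)},
        totals={"R01": total},
        names={"R01": "Region 01"},
        crs="local-km",
    )
    density = Raster(grid=g, values=np.ones(g.shape))
    return g, regions, density


def _stamp_facility(x: float, y: float, flags: bool,
                    catalog: IndicatorCatalog) -> pd.DataFrame:
    row = {"facility_id": "F0000", "lon": x, "lat": y, "level": "tertiary"}
    for name in catalog.indicators():
        row[name] = flags
    return pd.DataFrame([row])


def known_truth_scenario(name: str) -> dict:
    """Fixed analytic scenarios with closed-form expected outputs.

    ``single_facility_disc``: 100x100 unit-cell planar grid, uniform
    demand, one fully-capable facility at the window center; at 4 km/h and
    a 2 h threshold the covered set is the disc of radius 8 km around the
    facility, so the expected type-1 cell count is the exhaustive count of
    cell centroids inside that disc.

    ``full_coverage`` / ``no_coverage``: 10x10 window where the single
    central facility covers everything / is capable of nothing.

    ``two_region_contrast``: two half-window regions, many fully-capable
    facilities in the west, none in the east; the west must come out
    strictly better on all three service medians and on type-1 share.
    """
    catalog = default_catalog()
    params = TravelParams(speed_kmh=4.0, threshold_h=2.0, distance_mode="planar")
    if name == "single_facility_disc":
        g, regions, density = _planar_world(100, 100, total=1e5)
        cx = cy = 50.0
        facilities = _stamp_facility(cx, cy, True, catalog)
        radius = params.speed_kmh * params.threshold_h  # 8 km
        xx, yy = g.cell_centers()
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
        expected = {
            "radius_km": radius,
            "type1_cells": int(inside.sum()),
            "type1_pop_pct": 100.0 * inside.sum() / inside.size,
        }
    elif name == "full_coverage":
        g, regions, density = _planar_world(10, 10, total=1e4)
        facilities = _stamp_facility(5.0, 5.0, True, catalog)
        expected = {"type1_pop_pct": 100.0}
    elif name == "no_coverage":
        g, regions, density = _planar_world(10, 10, total=1e4)
        facilities = _stamp_facility(5.0, 5.0, False, catalog)
        expected = {"type8_pop_pct": 100.0}
    elif name == "two_region_contrast":
        g = GridSpec(nrows=60, ncols=120, xmin=0.0, ymin=0.0,
                     cellsize=1.0, crs="local-km")
        west, east = box(0, 0, 60, 60), box(60, 0, 120, 60)
        regions = RegionSet(
            region_ids=["R01", "R02"],
            geometries={"R01": west, "R02": east},
            totals={"R01": 1e5, "R02": 1e5},
            names={"R01": "Dense West", "R02": "Sparse East"},
            crs="local-km",
        )
        density = Raster(grid=g, values=np.ones(g.shape))
        rng = np.random.default_rng([7, _STAGE_FACILITIES])
        n_fac = 25
        rows = []
        for i in range(n_fac):
            row = {
                "facility_id": f"F{i:04d}",
                "lon": float(rng.uniform(0, 60)),
                "lat": float(rng.uniform(0, 60)),
                "level": "primary",
            }
            for ind in catalog.indicators():
                row[ind] = True
            rows.append(row)
        facilities = pd.DataFrame(rows)
        expected = {"dense_region": "R01", "sparse_region": "R02"}
    else:
        raise ValueError(f"unknown scenario {name!r}")
    return {
        "grid": g,
        "regions": regions,
        "density": density,
        "facilities": facilities,
        "catalog": catalog,
        "params": params,
        "expected": expected,
    }
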