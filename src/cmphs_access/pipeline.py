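"""Run configuration, table IO, and the end-to-end pipeline.

The full procedure chains: facility capability classification ->
dasymetric demand redistribution -> nearest-neighbour travel-time surface
per service package -> timely-access masks -> 8-type zone overlay ->
regional travel-time summary.  ``run_pipeline`` executes all stages from a
:class:`RunConfig` and writes the report bundle (CSV reports, ASCII-grid
rasters, and a machine-readable manifest with input checksums); any stage
failure aborts with a stage-tagged error and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import (
    IndicatorCatalog,
    classify_capability,
    indicator_coverage,
    level_capability_summary,
    load_catalog,
    validate_facility_table,
)
from .demand import assign_cells_to_regions, redistribute
from .grids import WGS84, Raster, read_ascii_grid, RegionSet, write_ascii_grid
from .overlay import classify_zones, rounded_zone_shares, zone_shares
from .summary import summarize
from .synthetic import Scenario
from .travel import TravelParams, coverage_mask, nearest_time_surface

__all__ = [
    "RunConfig",
    "read_facility_csv",
    "write_facility_csv",
    "read_totals_csv",
    "read_capability_csv",
    "write_scenario",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SERVICES = ("ANC", "ID", "PNC")

_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no"}


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    facilities_csv: str
    density_grid: str
    regions_geojson: str
    totals_csv: str | None = None
    catalog_yaml: str | None = None
    out_dir: str = "results"
    rule: str = "all"
    k: int | None = None
    travel: TravelParams = field(default_factory=TravelParams)
    weighting: str = "population"
    area_mode: str = "uniform"
    crs: str = WGS84
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        travel = TravelParams(**doc.pop("travel", {}))
        return cls(travel=travel, **doc)

    def validate(self) -> None:
        for label, p in (
            ("facilities_csv", self.facilities_csv),
            ("density_grid", self.density_grid),
            ("regions_geojson", self.regions_geojson),
        ):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label}: {p}")
        for label, p in (("totals_csv", self.totals_csv),
                         ("catalog_yaml", self.catalog_yaml)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label}: {p}")
        if self.weighting not in {"population", "unweighted"}:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.area_mode not in {"uniform", "cosine"}:
            raise ValueError(f"unknown area mode {self.area_mode!r}")


def _coerce_flag(value, column: str):
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"cannot parse flag value {value!r} in column {column!r}")


def read_facility_csv(path, catalog: IndicatorCatalog) -> pd.DataFrame:
    """Read and validate a facility CSV.

    Expects header columns ``facility_id, lon, lat, level`` followed by one
    flag column per indicator; flag cells may use 0/1, true/false, yes/no.
    """
    raw = pd.read_csv(path, dtype={"facility_id": str})
    meta = {"facility_id", "lon", "lat", "level"}
    for col in raw.columns:
        if col not in meta:
            raw[col] = [_coerce_flag(v, col) for v in raw[col]]
    table = validate_facility_table(raw, catalog)
    logger.info("read %d facilities from %s", len(table), path)
    return table


def write_facility_csv(facilities: pd.DataFrame, path,
                       catalog: IndicatorCatalog) -> None:
    out = facilities[["facility_id", "lon", "lat", "level"]].copy()
    for name in catalog.indicators():
        out[name] = facilities[name].astype(int)
    out.to_csv(path, index=False)


def read_totals_csv(path) -> dict[str, float]:
    """Totals CSV with columns ``region_id, total_wra``."""
    df = pd.read_csv(path, dtype={"region_id": str})
    missing = {"region_id", "total_wra"} - set(df.columns)
    if missing:
        raise ValueError(f"totals CSV missing columns: {sorted(missing)}")
    return dict(zip(df["region_id"], df["total_wra"].astype(float)))


def read_capability_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"facility_id": str})
    for svc in SERVICES:
        df[svc] = [_coerce_flag(v, svc) for v in df[svc]]
    return df


def write_scenario(scenario: Scenario, out_dir) -> dict[str, Path]:
    """Write a synthetic scenario in the exact input dialects the pipeline
    consumes: facilities.csv, density.asc, regions.geojson, totals.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "facilities": out / "facilities.csv",
        "density": out / "density.asc",
        "regions": out / "regions.geojson",
        "totals": out / "totals.csv",
    }
    write_facility_csv(scenario.facilities, paths["facilities"], scenario.catalog)
    write_ascii_grid(scenario.density, paths["density"])
    scenario.regions.to_geojson(paths["regions"])
    pd.DataFrame(
        {
            "region_id": scenario.regions.sorted_ids(),
            "total_wra": [scenario.regions.totals[r]
                          for r in scenario.regions.sorted_ids()],
        }
    ).to_csv(paths["totals"], index=False)
    return paths


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.out_dir``.

    Returns the in-memory results (tables, rasters, masks) keyed by name.
    """
    logging.basicConfig(level=config.log_level)
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        written.append(path)

    stage = "load"
    try:
        catalog = load_catalog(config.catalog_yaml)
        facilities = read_facility_csv(config.facilities_csv, catalog)
        density = read_ascii_grid(config.density_grid, crs=config.crs)
        regions = RegionSet.from_geojson(config.regions_geojson, crs=config.crs)
        if config.totals_csv is not None:
            regions = regions.with_totals(read_totals_csv(config.totals_csv))
        if not regions.totals:
            raise ValueError("no region totals provided (GeoJSON or totals CSV)")

        stage = "classify"
        capability = classify_capability(facilities, catalog,
                                         rule=config.rule, k=config.k)
        coverage_report = indicator_coverage(facilities, catalog)
        level_report = level_capability_summary(capability, facilities)

        stage = "redistribute"
        assignment, region_order = assign_cells_to_regions(density, regions)
        demand = redistribute(density, regions, assignment, region_order)

        stage = "access"
        surfaces: dict[str, Raster] = {}
        masks: dict[str, np.ndarray] = {}
        for svc in SERVICES:
            surfaces[svc] = nearest_time_surface(
                density.grid, facilities, capability, svc, config.travel
            )
            masks[svc] = coverage_mask(surfaces[svc], config.travel)

        stage = "overlay"
        study = demand.valid & (assignment >= 0)
        zones = classify_zones(masks["ANC"], masks["ID"], masks["PNC"],
                               study_mask=study)
        shares = zone_shares(zones, demand, cell_area=config.area_mode)

        stage = "summarize"
        regional = pd.concat(
            [summarize(surfaces[svc], demand, assignment, region_order, svc,
                       weighting=config.weighting)
             for svc in SERVICES],
            ignore_index=True,
        )

        stage = "write"
        emit("capability.csv",
             lambda p: capability.assign(
                 **{s: capability[s].astype(int) for s in SERVICES}
             ).to_csv(p, index=False))
        emit("indicator_coverage.csv",
             lambda p: coverage_report.to_csv(p, index=False))
        emit("level_capability.csv",
             lambda p: level_report.to_csv(p, index=False))
        emit("demand.asc", lambda p: write_ascii_grid(demand, p))
        for svc in SERVICES:
            emit(f"travel_time_{svc.lower()}.asc",
                 lambda p, s=svc: write_ascii_grid(surfaces[s], p))
        emit("zones.asc",
             lambda p: write_ascii_grid(
                 Raster(demand.grid, np.where(zones > 0, zones, np.nan)), p,
                 nodata=0))
        emit("zone_shares.csv",
             lambda p: rounded_zone_shares(shares).to_csv(p, index=False))
        emit("regional_times.csv", lambda p: regional.to_csv(p, index=False))

        manifest = {
            "package": "cmphs-access",
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                "rule": config.rule,
                "k": config.k,
                "travel": asdict(config.travel),
                "weighting": config.weighting,
                "area_mode": config.area_mode,
                "crs": config.crs,
            },
            "inputs": {
                name: _sha256(path)
                for name, path in {
                    "facilities_csv": config.facilities_csv,
                    "density_grid": config.density_grid,
                    "regions_geojson": config.regions_geojson,
                    "totals_csv": config.totals_csv,
                }.items()
                if path is not None
            },
            "outputs": sorted(p.name for p in written) + ["manifest.json"],
        }
        emit("manifest.json",
             lambda p: Path(p).write_text(json.dumps(manifest, indent=2)))
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "catalog": catalog,
        "facilities": facilities,
        "capability": capability,
        "indicator_coverage": coverage_report,
        "level_capability": level_report,
        "assignment": assignment,
        "region_order": region_order,
        "demand": demand,
        "surfaces": surfaces,
        "masks": masks,
        "zones": zones,
        "zone_shares": shares,
        "regional_times": regional,
        "manifest": manifest,
    }
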