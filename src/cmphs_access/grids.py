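"""Georeferenced grid container, ESRI ASCII grid IO, and region geometries.

Conventions used throughout the package:

* raster values are stored row-major from the **top-left** corner, so
  ``values[0, 0]`` is the north-west cell;
* cells are half-open intervals of side ``cellsize``; the centroid of cell
  ``(row, col)`` sits at a half-cell offset from the corner;
* nodata is represented internally as ``NaN``;
* the CRS is an opaque identifier string — the pipeline never reprojects,
  it only refuses to combine layers whose identifiers differ.  Use
  ``"EPSG:4326"`` for lon/lat degrees and any other label (for example
  ``"local-km"``) for planar coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "GridSpec",
    "Raster",
    "RegionSet",
    "read_ascii_grid",
    "write_ascii_grid",
]

WGS84 = "EPSG:4326"


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid: shape, lower-left corner, cell size, CRS."""

    nrows: int
    ncols: int
    xmin: float
    ymin: float
    cellsize: float
    crs: str = WGS84

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid must have positive shape")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be > 0")

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cellsize

    @property
    def ymax(self) -> float:
        return self.ymin + self.nrows * self.cellsize

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Centroid coordinates as two ``(nrows, ncols)`` arrays ``(x, y)``.

        Row 0 is the northernmost row, so y decreases with the row index.
        """
        cs = self.cellsize
        x = self.xmin + (np.arange(self.ncols) + 0.5) * cs
        y = self.ymax - (np.arange(self.nrows) + 0.5) * cs
        xx, yy = np.meshgrid(x, y)
        return xx, yy

    def compatible_with(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.xmin, other.xmin)
            and np.isclose(self.ymin, other.ymin)
            and np.isclose(self.cellsize, other.cellsize)
            and self.crs == other.crs
        )


@dataclass
class Raster:
    """A grid of float values on a :class:`GridSpec`; nodata cells are NaN."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        return ~np.isnan(self.values)

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(grid=self.grid, values=np.asarray(values, dtype=float))


def write_ascii_grid(raster: Raster, path, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (.asc).  NaN and +inf become the nodata value."""
    vals = raster.values.copy()
    vals[~np.isfinite(vals)] = nodata
    g = raster.grid
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.xmin!r}\n"
        f"yllcorner {g.ymin!r}\n"
        f"cellsize {g.cellsize!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path, crs: str = WGS84) -> Raster:
    """Read an ESRI ASCII grid; nodata cells become NaN.

    The .asc dialect carries no CRS, so the caller supplies the identifier.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid header missing {key!r}")
    grid = GridSpec(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        xmin=header["xllcorner"],
        ymin=header["yllcorner"],
        cellsize=header["cellsize"],
        crs=crs,
    )
    if data.shape != grid.shape:
        raise ValueError(f"data shape {data.shape} does not match header {grid.shape}")
    if "nodata_value" in header:
        data[data == header["nodata_value"]] = np.nan
    return Raster(grid=grid, values=data)


@dataclass
class RegionSet:
    """Administrative regions: id -> polygon, optional name and WRA total.

    ``totals`` holds the announced number of women of reproductive age per
    region (the authoritative counts the demand raster is rescaled to).
    """

    region_ids: list[str]
    geometries: dict[str, BaseGeometry]
    totals: dict[str, float] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)
    crs: str = WGS84

    def __post_init__(self) -> None:
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be unique")
        missing = [r for r in self.region_ids if r not in self.geometries]
        if missing:
            raise ValueError(f"regions without geometry: {missing}")
        for rid, t in self.totals.items():
            if t < 0:
                raise ValueError(f"negative total for region {rid!r}")

    def sorted_ids(self) -> list[str]:
        return sorted(self.region_ids)

    def with_totals(self, totals: dict[str, float]) -> "RegionSet":
        unknown = set(totals) - set(self.region_ids)
        if unknown:
            raise ValueError(f"totals for unknown regions: {sorted(unknown)}")
        return replace(self, totals=dict(totals))

    # -- GeoJSON ----------------------------------------------------------
    def to_geojson(self, path) -> None:
        features = []
        for rid in self.region_ids:
            props = {"region_id": rid, "name": self.names.get(rid, rid)}
            if rid in self.totals:
                props["total_wra"] = self.totals[rid]
            features.append(
                {
                    "type": "Feature",
                    "properties": props,
                    "geometry": shapely_mapping(self.geometries[rid]),
                }
            )
        doc = {"type": "FeatureCollection", "features": features}
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_geojson(cls, path, crs: str = WGS84) -> "RegionSet":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("type") != "FeatureCollection":
            raise ValueError("expected a GeoJSON FeatureCollection")
        ids: list[str] = []
        geoms: dict[str, BaseGeometry] = {}
        names: dict[str, str] = {}
        totals: dict[str, float] = {}
        for feat in doc["features"]:
            props = feat.get("properties") or {}
            if "region_id" not in props:
                raise ValueError("feature missing 'region_id' property")
            rid = str(props["region_id"])
            ids.append(rid)
            geoms[rid] = shapely_shape(feat["geometry"])
            names[rid] = str(props.get("name", rid))
            if "total_wra" in props:
                totals[rid] = float(props["total_wra"])
        return cls(region_ids=ids, geometries=geoms, totals=totals, names=names, crs=crs)
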