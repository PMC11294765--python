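"""Haversine distances and nearest-facility travel-time surfaces."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmphs_access.grids import GridSpec
from cmphs_access.travel import (
    EARTH_RADIUS_KM,
    TravelParams,
    coverage_mask,
    great_circle_km,
    nearest_time_surface,
)
from conftest import random_facility_table


def facilities_at(points, catalog, capable=True):
    """Facility table at explicit (lon, lat) points, all flags = capable."""
    rows = []
    for i, (lon, lat) in enumerate(points):
        row = {"facility_id": f"F{i:04d}", "lon": lon, "lat": lat,
               "level": "primary"}
        for name in catalog.indicators():
            row[name] = capable
        rows.append(row)
    return pd.DataFrame(rows)


def capability_all(facilities, value=True):
    return pd.DataFrame(
        {"facility_id": facilities["facility_id"], "ANC": value, "ID": value,
         "PNC": value}
    )


def brute_force_hours(grid, facilities, params):
    """Independent exhaustive per-cell minimum over all facilities."""
    xx, yy = grid.cell_centers()
    best = np.full(grid.shape, np.inf)
    for _, fac in facilities.iterrows():
        if params.distance_mode == "planar":
            d = np.hypot(xx - fac["lon"], yy - fac["lat"])
        else:
            d = great_circle_km(yy, xx, fac["lat"], fac["lon"],
                                radius=params.earth_radius_km)
        best = np.minimum(best, d)
    return best / params.speed_kmh


class TestGreatCircle:
    def test_identity_is_zero(self):
        assert great_circle_km(0, 0, 0, 0) == 0.0

    def test_one_degree_on_equator(self):
        # closed form: 2*pi*R/360 with R = 6371 km
        expect = 2 * np.pi * EARTH_RADIUS_KM / 360
        assert great_circle_km(0, 0, 0, 1) == pytest.approx(expect, abs=1e-9)
        assert great_circle_km(0, 0, 0, 1) == pytest.approx(111.195, abs=1e-3)

    def test_antipodal_clamps_instead_of_nan(self):
        d = great_circle_km(0, 0, 0, 180)
        assert d == pytest.approx(np.pi * EARTH_RADIUS_KM, rel=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        lat1=st.floats(-90, 90), lon1=st.floats(-180, 180),
        lat2=st.floats(-90, 90), lon2=st.floats(-180, 180),
    )
    def test_symmetric_and_nonnegative(self, lat1, lon1, lat2, lon2):
        d_ab = great_circle_km(lat1, lon1, lat2, lon2)
        d_ba = great_circle_km(lat2, lon2, lat1, lon1)
        assert d_ab == d_ba
        assert d_ab >= 0


class TestNearestSurface:
    def test_facility_at_cell_centroid_reads_zero(self, catalog):
        grid = GridSpec(nrows=3, ncols=3, xmin=0, ymin=0, cellsize=1.0)
        xx, yy = grid.cell_centers()
        fac = facilities_at([(xx[1, 1], yy[1, 1])], catalog)
        surface = nearest_time_surface(grid, fac, capability_all(fac), "ANC")
        assert surface.values[1, 1] == 0.0

    def test_eight_km_north_takes_two_hours(self, catalog):
        grid = GridSpec(nrows=1, ncols=1, xmin=0.0, ymin=-0.005,
                        cellsize=0.01)
        xx, yy = grid.cell_centers()
        dlat = 8.0 / (2 * np.pi * EARTH_RADIUS_KM / 360)  # 8 km in degrees
        fac = facilities_at([(xx[0, 0], yy[0, 0] + dlat)], catalog)
        surface = nearest_time_surface(grid, fac, capability_all(fac), "ANC")
        assert surface.values[0, 0] == pytest.approx(2.0, rel=1e-9)

    def test_matches_brute_force_small_network(self, catalog):
        rng = np.random.default_rng(10)
        grid = GridSpec(nrows=30, ncols=30, xmin=33.0, ymin=-19.0,
                        cellsize=0.02)
        fac = random_facility_table(rng, 12, catalog, p=1.0,
                                    lon_range=(33.0, 33.6),
                                    lat_range=(-19.0, -18.4))
        params = TravelParams()
        surface = nearest_time_surface(grid, fac, capability_all(fac), "ANC",
                                       params)
        np.testing.assert_array_equal(
            surface.values, brute_force_hours(grid, fac, params)
        )

    def test_matches_brute_force_with_kdtree_path(self, catalog):
        # >64 facilities exercises the k-d-tree acceleration
        rng = np.random.default_rng(20)
        grid = GridSpec(nrows=25, ncols=25, xmin=33.0, ymin=-19.0,
                        cellsize=0.02)
        fac = random_facility_table(rng, 90, catalog, p=1.0,
                                    lon_range=(33.0, 33.5),
                                    lat_range=(-19.0, -18.5))
        params = TravelParams()
        surface = nearest_time_surface(grid, fac, capability_all(fac), "ANC",
                                       params)
        np.testing.assert_array_equal(
            surface.values, brute_force_hours(grid, fac, params)
        )

    def test_planar_mode_matches_euclidean_oracle(self, catalog):
        rng = np.random.default_rng(30)
        grid = GridSpec(nrows=20, ncols=20, xmin=0, ymin=0, cellsize=1.0,
                        crs="local-km")
        pts = [(float(x), float(y))
               for x, y in rng.uniform(0, 20, size=(8, 2))]
        fac = facilities_at(pts, catalog)
        params = TravelParams(distance_mode="planar")
        surface = nearest_time_surface(grid, fac, capability_all(fac), "ANC",
                                       params)
        np.testing.assert_array_equal(
            surface.values, brute_force_hours(grid, fac, params)
        )

    def test_adding_facility_never_increases_times(self, catalog):
        rng = np.random.default_rng(4)
        grid = GridSpec(nrows=15, ncols=15, xmin=33, ymin=-19, cellsize=0.05)
        fac = random_facility_table(rng, 10, catalog, p=1.0)
        more = random_facility_table(np.random.default_rng(5), 11, catalog,
                                     p=1.0)
        more["facility_id"] = [f"G{i:04d}" for i in range(len(more))]
        small = nearest_time_surface(grid, fac, capability_all(fac), "ID")
        both = pd.concat([fac, more], ignore_index=True)
        large = nearest_time_surface(grid, both, capability_all(both), "ID")
        assert np.all(large.values <= small.values + 1e-15)

    def test_doubling_speed_halves_times(self, catalog):
        rng = np.random.default_rng(6)
        grid = GridSpec(nrows=10, ncols=10, xmin=33, ymin=-19, cellsize=0.05)
        fac = random_facility_table(rng, 5, catalog, p=1.0)
        slow = nearest_time_surface(grid, fac, capability_all(fac), "PNC",
                                    TravelParams(speed_kmh=4.0))
        fast = nearest_time_surface(grid, fac, capability_all(fac), "PNC",
                                    TravelParams(speed_kmh=8.0))
        np.testing.assert_allclose(fast.values, slow.values / 2.0, rtol=1e-12)

    def test_distance_tie_resolved_to_smallest_id(self, catalog):
        grid = GridSpec(nrows=1, ncols=1, xmin=0, ymin=0, cellsize=1.0,
                        crs="local-km")
        # facilities equidistant (2 km left and right of the centroid)
        fac = facilities_at([(2.5, 0.5), (-1.5, 0.5)], catalog)
        fac["facility_id"] = ["F0001", "F0000"]
        _, nearest = nearest_time_surface(
            grid, fac, capability_all(fac), "ANC",
            TravelParams(distance_mode="planar"), return_nearest=True,
        )
        assert nearest[0, 0] == "F0000"

    def test_no_capable_facility_warns_all_infinite(self, catalog, caplog):
        grid = GridSpec(nrows=2, ncols=2, xmin=0, ymin=0, cellsize=1.0)
        fac = facilities_at([(0.5, 0.5)], catalog, capable=False)
        with caplog.at_level(logging.WARNING):
            surface = nearest_time_surface(
                grid, fac, capability_all(fac, value=False), "ANC"
            )
        assert np.isinf(surface.values).all()
        assert any("all-infinite" in r.message for r in caplog.records)

    def test_empty_facility_table_errors(self, catalog):
        grid = GridSpec(nrows=2, ncols=2, xmin=0, ymin=0, cellsize=1.0)
        fac = facilities_at([(0.5, 0.5)], catalog).iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            nearest_time_surface(grid, fac, capability_all(fac), "ANC")


class TestCoverageMask:
    def test_threshold_is_closed(self):
        grid = GridSpec(nrows=1, ncols=3, xmin=0, ymin=0, cellsize=1.0)
        from cmphs_access.grids import Raster

        surface = Raster(grid, np.array([[1.99, 2.0, 2.01]]))
        mask = coverage_mask(surface, TravelParams(threshold_h=2.0))
        assert mask.tolist() == [[True, True, False]]

    def test_infinite_never_covered(self):
        grid = GridSpec(nrows=1, ncols=2, xmin=0, ymin=0, cellsize=1.0)
        from cmphs_access.grids import Raster

        surface = Raster(grid, np.array([[np.inf, 0.5]]))
        mask = coverage_mask(surface)
        assert mask.tolist() == [[False, True]]

    def test_coverage_monotone_in_threshold_and_speed(self, catalog):
        rng = np.random.default_rng(8)
        grid = GridSpec(nrows=20, ncols=20, xmin=33, ymin=-19, cellsize=0.05)
        fac = random_facility_table(rng, 6, catalog, p=1.0)
        cap = capability_all(fac)
        base = nearest_time_surface(grid, fac, cap, "ANC",
                                    TravelParams(speed_kmh=4.0))
        frac = coverage_mask(base, TravelParams(threshold_h=2.0)).mean()
        frac_hi_thresh = coverage_mask(base, TravelParams(threshold_h=3.0)).mean()
        fast = nearest_time_surface(grid, fac, cap, "ANC",
                                    TravelParams(speed_kmh=6.0))
        frac_fast = coverage_mask(fast, TravelParams(threshold_h=2.0)).mean()
        assert frac_hi_thresh >= frac
        assert frac_fast >= frac
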