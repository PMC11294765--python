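import numpy as np
import pandas as pd
import pytest

from cmphs_access import default_catalog
from cmphs_access.grids import RegionSet
from cmphs_access.pipeline import write_facility_csv
from cmphs_access.grids import write_ascii_grid


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def random_facility_table(rng, n, catalog, p=0.5, lon_range=(30.0, 40.0),
                          lat_range=(-25.0, -15.0)):
    """Random facility table with Bernoulli(p) flags; helper, not a fixture."""
    table = pd.DataFrame(
        {
            "facility_id": [f"F{i:04d}" for i in range(n)],
            "lon": rng.uniform(*lon_range, size=n),
            "lat": rng.uniform(*lat_range, size=n),
            "level": rng.choice(["primary", "secondary", "tertiary"], size=n),
        }
    )
    for name in catalog.indicators():
        table[name] = rng.random(n) < p
    return table


def write_scenario_inputs(tmp_path, grid, regions: RegionSet, density,
                          facilities, catalog):
    """Write pipeline input files for an in-memory scenario; returns paths."""
    paths = {
        "facilities": tmp_path / "facilities.csv",
        "density": tmp_path / "density.asc",
        "regions": tmp_path / "regions.geojson",
        "totals": tmp_path / "totals.csv",
    }
    write_facility_csv(facilities, paths["facilities"], catalog)
    write_ascii_grid(density, paths["density"])
    regions.to_geojson(paths["regions"])
    pd.DataFrame(
        {
            "region_id": regions.sorted_ids(),
            "total_wra": [regions.totals[r] for r in regions.sorted_ids()],
        }
    ).to_csv(paths["totals"], index=False)
    return paths
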