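import numpy as np
import pytest
import xarray as xr

from airburden.satellite_qc import filter_retrievals, regrid_area_weighted
from airburden.synthetic import (GridConfig, ScenarioConfig, generate_scenario,
                                 synthesize_meteorology, synthesize_satellite)


def tiny_config(**overrides) -> ScenarioConfig:
    """A 12x12-cell, 20-station scenario that runs in seconds."""
    base = dict(grid=GridConfig(lat_min=30, lat_max=33, lon_min=110, lon_max=113),
                n_stations=20)
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small default-style scenario with meteorology and NO2 satellite attached."""
    scen = generate_scenario(tiny_config(), seed=7)
    synthesize_meteorology(scen, seed=8)
    synthesize_satellite(scen, seed=9, pollutants=["NO2"])
    return scen


def qc_and_regrid(scenario, pollutant: str) -> xr.DataArray:
    """Filter and regrid one pollutant's satellite series to the analysis grid."""
    series = scenario.satellite[pollutant]
    cubes = [regrid_area_weighted(filter_retrievals(series.field(i)).field,
                                  scenario.grid)
             for i in range(len(series))]
    return xr.DataArray(np.stack(cubes),
                        coords={"time": series.time,
                                "lat": scenario.grid.lat_centers,
                                "lon": scenario.grid.lon_centers},
                        dims=("time", "lat", "lon"), name="satellite")


@pytest.fixture(scope="session")
def tiny_no2_table(tiny_scenario):
    """Assembled NO2 feature table for the tiny scenario."""
    from airburden import features
    sat = qc_and_regrid(tiny_scenario, "NO2")
    return features.build_table(tiny_scenario.observations, sat,
                                tiny_scenario.meteorology,
                                tiny_scenario.static_covariates(),
                                tiny_scenario.grid, "NO2")
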