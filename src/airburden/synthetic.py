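"""Self-contained synthetic study scenario with known ground truth.

The generator emulates the data stack of a national lockdown air-quality
study: smooth latent daily pollutant surfaces with year-specific levels and a
configurable in-window lockdown decrement; a spatially uneven station network
reporting noisy observations of the latent surface; satellite retrieval
fields that are noisy affine transforms of the truth with controlled QC
contamination; eight meteorological covariate fields, a subset of which is
made predictive of the truth; static elevation / land-use / population
covariates; rectangular analysis regions; and per-cause baseline mortality
rates. Because the truth is stored, every downstream stage (QC, regridding,
feature join, model fit, change statistics, burden) can be tested for
recovery without any external data.

Every stochastic draw is governed by a single integer seed via
``numpy.random.SeedSequence``; regeneration with the same configuration and
seed is bit-identical.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.ndimage import gaussian_filter

from .grid import GridSpec
from .satellite_qc import RetrievalField

POLLUTANTS = ("NO2", "SO2", "CO", "O3_8h")

#: the eight meteorological covariates carried by the pipeline
MET_VARS = ("D2m", "E", "Mbld", "surface_pressure", "T2m",
            "total_precipitation", "U10", "V10")

#: rough physical scale (offset, sd) for each meteorological variable
_MET_SCALES = {
    "D2m": (272.0, 6.0),              # K
    "E": (-1.5e-4, 8e-5),             # m of water equivalent / day
    "Mbld": (300.0, 120.0),           # J m-2
    "surface_pressure": (96000.0, 2500.0),  # Pa
    "T2m": (278.0, 7.0),              # K
    "total_precipitation": (1.5e-3, 1.0e-3),  # m / day
    "U10": (0.5, 2.5),                # m s-1
    "V10": (-0.3, 2.5),               # m s-1
}

LANDUSE_CLASSES = ("waters", "grassland", "urban", "forest", "agricultural")

MORTALITY_CAUSES = ("all_cause", "CVD", "RD", "COPD")


class GridConfig(BaseModel):
    lat_min: float = 30.0
    lat_max: float = 40.0
    lon_min: float = 110.0
    lon_max: float = 120.0
    resolution: float = 0.25

    @field_validator("resolution")
    @classmethod
    def _positive_resolution(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("grid resolution must be positive")
        return v

    def build(self) -> GridSpec:
        return GridSpec(self.lat_min, self.lat_max, self.lon_min, self.lon_max,
                        self.resolution)


class SatelliteConfig(BaseModel):
    """Affine observation model for the synthetic column retrievals.

    pixel value = gain * truth + offset + smooth bias + white noise.
    """
    gain: float = 1.0
    offset: float = 0.0
    bias_sd: float = 1.0     # sd of the smooth spatial bias field, product units
    noise_sd: float = 1.0    # sd of per-pixel white noise
    pixel_factor: int = 2    # pixels per analysis cell along each axis

    @field_validator("pixel_factor")
    @classmethod
    def _factor(cls, v: int) -> int:
        if v < 1:
            raise ValueError("pixel_factor must be >= 1")
        return v


class PollutantConfig(BaseModel):
    level: float                      # national mean concentration scale
    noise_sd: float                   # station observation noise sd
    seasonal_amplitude: float = 0.15  # relative amplitude of in-window trend
    weekend_factor: float = 0.92      # multiplicative weekend emission factor
    year_levels: dict[int, float] = Field(default_factory=dict)
    lockdown_decrement: float = 0.0   # fractional in-window reduction, target year
    satellite: SatelliteConfig = Field(default_factory=SatelliteConfig)

    @field_validator("lockdown_decrement")
    @classmethod
    def _decrement(cls, v: float) -> float:
        if not (0.0 <= v < 1.0):
            raise ValueError(f"lockdown_decrement must lie in [0, 1), got {v}")
        return v

    @field_validator("level", "noise_sd")
    @classmethod
    def _nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("pollutant level and noise_sd must be nonnegative")
        return v


class QCConfig(BaseModel):
    """Fraction of pixels forced to violate each QC rule, plus anomaly columns."""
    crf_fraction: float = 0.05
    reflectivity_fraction: float = 0.05
    sza_fraction: float = 0.05
    row_anomaly_cols: list[int] = Field(default_factory=lambda: [5, 17])

    @field_validator("crf_fraction", "reflectivity_fraction", "sza_fraction")
    @classmethod
    def _fraction(cls, v: float) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"contamination fraction must lie in [0, 1], got {v}")
        return v


class MetConfig(BaseModel):
    predictive_vars: list[str] = Field(
        default_factory=lambda: ["T2m", "surface_pressure", "U10", "V10"])
    correlation: float = 0.5          # per-cell corr of predictive vars w/ truth
    anchor_pollutant: str = "NO2"

    @field_validator("correlation")
    @classmethod
    def _rho(cls, v: float) -> float:
        if not (-1.0 <= v <= 1.0):
            raise ValueError("correlation must lie in [-1, 1]")
        return v

    @field_validator("predictive_vars")
    @classmethod
    def _vars(cls, v: list[str]) -> list[str]:
        bad = set(v) - set(MET_VARS)
        if bad:
            raise ValueError(f"unknown meteorological variables: {sorted(bad)}")
        return v


def _default_pollutants() -> dict[str, PollutantConfig]:
    return {
        "NO2": PollutantConfig(level=30.0, noise_sd=3.0, lockdown_decrement=0.20,
                               satellite=SatelliteConfig(bias_sd=1.5, noise_sd=1.5)),
        "SO2": PollutantConfig(level=15.0, noise_sd=1.5, lockdown_decrement=0.26,
                               satellite=SatelliteConfig(bias_sd=0.8, noise_sd=0.8)),
        "CO": PollutantConfig(level=1.0, noise_sd=0.10, lockdown_decrement=0.07,
                              satellite=SatelliteConfig(bias_sd=0.05, noise_sd=0.05)),
        # the target-year level bump emulates the observed ozone increase
        "O3_8h": PollutantConfig(level=80.0, noise_sd=6.0, lockdown_decrement=0.0,
                                 year_levels={2018: 1.0, 2019: 1.0, 2020: 1.013},
                                 satellite=SatelliteConfig(bias_sd=4.0, noise_sd=4.0)),
    }


def _default_rates() -> dict[str, float]:
    # annual deaths per person, broadly representative national values;
    # user-editable, not authoritative epidemiology
    return {"all_cause": 0.00707, "CVD": 0.00310, "RD": 0.00068, "COPD": 0.00090}


class ScenarioConfig(BaseModel):
    grid: GridConfig = Field(default_factory=GridConfig)
    years: list[int] = Field(default_factory=lambda: [2018, 2019, 2020])
    target_year: int = 2020
    window_start: tuple[int, int] = (1, 23)   # (month, day), inclusive
    window_end: tuple[int, int] = (3, 31)     # (month, day), inclusive
    pollutants: dict[str, PollutantConfig] = Field(default_factory=_default_pollutants)
    n_stations: int = 200
    station_density_skew: float = 1.0  # sampling weight ∝ population ** skew
    met: MetConfig = Field(default_factory=MetConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    baseline_rates: dict[str, float] = Field(default_factory=_default_rates)
    n_bumps: int = 6                   # Gaussian bumps in the latent surface
    population_mean_density: float = 400.0  # persons per km^2

    @field_validator("pollutants")
    @classmethod
    def _pollutant_names(cls, v: dict[str, PollutantConfig]) -> dict[str, PollutantConfig]:
        bad = set(v) - set(POLLUTANTS)
        if bad:
            raise ValueError(f"unknown pollutants: {sorted(bad)}")
        if not v:
            raise ValueError("at least one pollutant required")
        return v

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if not self.years:
            raise ValueError("at least one year required")
        if self.target_year not in self.years:
            raise ValueError(f"target_year {self.target_year} not in years {self.years}")
        try:
            for y in self.years:
                s = dt.date(y, *self.window_start)
                e = dt.date(y, *self.window_end)
                if e < s:
                    raise ValueError("window_end precedes window_start")
        except ValueError as err:
            raise ValueError(f"invalid analysis window: {err}") from err
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")
        return self


def window_dates(year: int, start: tuple[int, int] = (1, 23),
                 end: tuple[int, int] = (3, 31)) -> pd.DatetimeIndex:
    """Calendar dates of the analysis window in one year (inclusive).

    Feb 29 is included only in years where it exists, so the window holds 69
    days in leap years and 68 otherwise for the default Jan 23 – Mar 31 span.
    """
    return pd.date_range(dt.date(year, *start), dt.date(year, *end), freq="D")


@dataclass
class SatelliteSeries:
    """Stacked daily retrieval fields for one pollutant, with contamination record."""

    pollutant: str
    pixel_grid: GridSpec
    time: pd.DatetimeIndex
    values: np.ndarray                # (t, ny, nx)
    cloud_radiance_fraction: np.ndarray
    terrain_reflectivity: np.ndarray
    solar_zenith_angle: np.ndarray
    row_anomaly: np.ndarray           # (ny, nx), time-invariant
    contaminated: np.ndarray          # (t, ny, nx) union of injected violations

    def field(self, i: int) -> RetrievalField:
        return RetrievalField(
            values=self.values[i],
            cloud_radiance_fraction=self.cloud_radiance_fraction[i],
            terrain_reflectivity=self.terrain_reflectivity[i],
            solar_zenith_angle=self.solar_zenith_angle[i],
            row_anomaly=self.row_anomaly,
            lat_edges=self.pixel_grid.lat_edges,
            lon_edges=self.pixel_grid.lon_edges,
        )

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class LatentScenario:
    """Complete synthetic study: ground truth plus all synthetic observations."""

    config: ScenarioConfig
    grid: GridSpec
    years: list[int]
    dates: pd.DatetimeIndex                       # all window days, all years
    truth: dict[str, xr.DataArray]                # pollutant -> (time, lat, lon)
    counterfactual: dict[str, xr.DataArray]       # target-year truth w/o decrement
    region_masks: dict[str, np.ndarray]
    population: np.ndarray                        # persons per cell
    elevation: np.ndarray                         # m
    landuse: dict[str, np.ndarray]                # class -> fraction per cell
    population_density: np.ndarray                # persons per km^2
    baseline_rates: dict[str, float]
    stations: pd.DataFrame                        # station_id, lat, lon
    observations: pd.DataFrame                    # station_id, lat, lon, date, pollutant, value
    seed: int
    meteorology: xr.Dataset | None = None
    satellite: dict[str, SatelliteSeries] = dc_field(default_factory=dict)

    @property
    def target_year(self) -> int:
        return self.config.target_year

    def year_dates(self, year: int) -> pd.DatetimeIndex:
        return window_dates(year, self.config.window_start, self.config.window_end)

    def truth_for_year(self, pollutant: str, year: int) -> xr.DataArray:
        da = self.truth[pollutant]
        return da.sel(time=da.time.dt.year == year)

    def static_covariates(self) -> xr.Dataset:
        coords = {"lat": self.grid.lat_centers, "lon": self.grid.lon_centers}
        data = {
            "elevation": (("lat", "lon"), self.elevation),
            "population_density": (("lat", "lon"), self.population_density),
        }
        for cls, frac in self.landuse.items():
            data[f"landuse_{cls}"] = (("lat", "lon"), frac)
        return xr.Dataset(data, coords=coords)

    def export(self, outdir: str | Path) -> None:
        """Write the scenario as NetCDF grids, a stations CSV, and a YAML config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for pol, da in self.truth.items():
            ds = da.to_dataset(name="concentration")
            ds["concentration"].attrs["units"] = "mg m-3" if pol == "CO" else "ug m-3"
            ds.to_netcdf(outdir / f"truth_{pol}.nc", engine="scipy")
        self.static_covariates().to_netcdf(outdir / "static.nc", engine="scipy")
        if self.meteorology is not None:
            self.meteorology.to_netcdf(outdir / "meteorology.nc", engine="scipy")
        obs = self.observations.copy()
        obs["date"] = obs["date"].dt.strftime("%Y-%m-%d")
        obs[["station_id", "lat", "lon", "date", "pollutant", "value"]].to_csv(
            outdir / "stations.csv", index=False)
        masks = xr.Dataset(
            {name: (("lat", "lon"), m.astype(np.int8)) for name, m in self.region_masks.items()},
            coords={"lat": self.grid.lat_centers, "lon": self.grid.lon_centers})
        masks.to_netcdf(outdir / "region_masks.nc", engine="scipy")
        with open(outdir / "scenario_config.yaml", "w") as fh:
            yaml.safe_dump(self.config.model_dump(mode="json"), fh, sort_keys=True)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma_cells: float = 4.0) -> np.ndarray:
    """Zero-mean, unit-sd smooth Gaussian random field."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="nearest")
    sd = raw.std()
    if sd == 0:
        return np.zeros(shape)
    return (raw - raw.mean()) / sd


def _bump_surface(rng: np.random.Generator, grid: GridSpec, n_bumps: int) -> np.ndarray:
    """Sum-of-Gaussian-bumps spatial surface, normalised to mean 1, min > 0."""
    lat = grid.lat_centers[:, None]
    lon = grid.lon_centers[None, :]
    surface = np.zeros(grid.shape)
    for _ in range(n_bumps):
        clat = rng.uniform(grid.lat_min, grid.lat_max)
        clon = rng.uniform(grid.lon_min, grid.lon_max)
        width = rng.uniform(0.08, 0.25) * (grid.lat_max - grid.lat_min)
        amp = rng.uniform(0.5, 1.5)
        surface += amp * np.exp(-((lat - clat) ** 2 + (lon - clon) ** 2) / (2 * width**2))
    # floor keeps every cell strictly positive so baselines are well defined
    surface = 0.3 + surface
    return surface / surface.mean()


def _temporal_factor(dates: pd.DatetimeIndex, amplitude: float,
                     weekend_factor: float) -> np.ndarray:
    """Smooth within-window trend times a weekday/weekend factor."""
    doy = dates.dayofyear.to_numpy(dtype=float)
    trend = 1.0 + amplitude * np.sin(2 * np.pi * (doy - 23.0) / 140.0)
    weekend = np.where(dates.dayofweek >= 5, weekend_factor, 1.0)
    return trend * weekend


def _default_region_masks(grid: GridSpec) -> dict[str, np.ndarray]:
    """National mask plus four rectangular toy agglomerations (BTH/YRD/PRD/Wuhan)."""
    ny, nx = grid.shape

    def rect(y0: float, y1: float, x0: float, x1: float) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool)
        m[int(y0 * ny):max(int(y1 * ny), int(y0 * ny) + 1),
          int(x0 * nx):max(int(x1 * nx), int(x0 * nx) + 1)] = True
        return m

    return {
        "national": np.ones(grid.shape, dtype=bool),
        "BTH": rect(0.70, 0.95, 0.55, 0.85),
        "YRD": rect(0.30, 0.55, 0.65, 0.95),
        "PRD": rect(0.05, 0.20, 0.35, 0.60),
        "Wuhan": rect(0.45, 0.55, 0.25, 0.35),
    }


def generate_scenario(config: ScenarioConfig, seed: int) -> LatentScenario:
    """Generate a complete scenario with known ground truth.

    The latent surface for each pollutant is a static sum-of-bumps spatial
    field scaled by a smooth seasonal trend, a weekday factor, and a
    year-specific level; inside the analysis window of the target year it is
    multiplied by (1 - lockdown_decrement), exactly, so the decrement identity
    holds cell by cell. Station observations add zero-mean Gaussian noise to
    the truth of the containing cell and are floored at zero (floored values
    are kept, not resampled).
    """
    ss = np.random.SeedSequence(seed)
    # fixed spawn order => reproducibility and stage independence
    s_surface, s_static, s_stations, s_obs = ss.spawn(4)
    grid = config.grid.build()

    dates_by_year = {y: window_dates(y, config.window_start, config.window_end)
                     for y in config.years}
    all_dates = pd.DatetimeIndex(np.concatenate(
        [d.values for y, d in sorted(dates_by_year.items())]))

    # --- static covariates -------------------------------------------------
    rng_static = np.random.default_rng(s_static)
    pop_field = _smooth_field(rng_static, grid.shape, sigma_cells=3.0)
    population_density = config.population_mean_density * np.exp(
        0.9 * pop_field - 0.5 * 0.9**2)
    population = population_density * grid.cell_areas_km2
    elevation = np.maximum(
        60.0 + 900.0 * np.abs(_smooth_field(rng_static, grid.shape, sigma_cells=5.0)), 0.0)
    raw = np.stack([np.exp(1.2 * _smooth_field(rng_static, grid.shape, sigma_cells=4.0))
                    for _ in LANDUSE_CLASSES])
    landuse = {cls: raw[i] / raw.sum(axis=0) for i, cls in enumerate(LANDUSE_CLASSES)}

    # --- latent truth ------------------------------------------------------
    rng_surface = np.random.default_rng(s_surface)
    truth: dict[str, xr.DataArray] = {}
    counterfactual: dict[str, xr.DataArray] = {}
    coords2d = {"lat": grid.lat_centers, "lon": grid.lon_centers}
    for pol in sorted(config.pollutants):
        pcfg = config.pollutants[pol]
        surface = _bump_surface(rng_surface, grid, config.n_bumps) * pcfg.level
        stacks = []
        for year in sorted(config.years):
            d = dates_by_year[year]
            factor = _temporal_factor(d, pcfg.seasonal_amplitude, pcfg.weekend_factor)
            ylevel = pcfg.year_levels.get(year, 1.0)
            cube = surface[None, :, :] * factor[:, None, None] * ylevel
            if year == config.target_year:
                counterfactual[pol] = xr.DataArray(
                    cube.copy(), coords={"time": d, **coords2d},
                    dims=("time", "lat", "lon"), name=pol)
                cube = cube * (1.0 - pcfg.lockdown_decrement)
            stacks.append(xr.DataArray(cube, coords={"time": d, **coords2d},
                                       dims=("time", "lat", "lon"), name=pol))
        truth[pol] = xr.concat(stacks, dim="time")

    # --- stations ----------------------------------------------------------
    rng_st = np.random.default_rng(s_stations)
    weights = np.maximum(population, 0.0) ** config.station_density_skew
    weights = weights.ravel() / weights.sum()
    cells = rng_st.choice(weights.size, size=config.n_stations, replace=True, p=weights)
    iy, ix = np.unravel_index(cells, grid.shape)
    lat = grid.lat_edges[iy] + rng_st.uniform(0, grid.resolution, config.n_stations)
    lon = grid.lon_edges[ix] + rng_st.uniform(0, grid.resolution, config.n_stations)
    stations = pd.DataFrame({
        "station_id": [f"S{i:04d}" for i in range(config.n_stations)],
        "lat": lat, "lon": lon,
    })

    # --- observations ------------------------------------------------------
    rng_obs = np.random.default_rng(s_obs)
    siy, six = grid.cell_index(stations["lat"].to_numpy(), stations["lon"].to_numpy())
    frames = []
    for pol in sorted(config.pollutants):
        pcfg = config.pollutants[pol]
        cube = truth[pol].values                     # (t, ny, nx)
        vals = cube[:, siy, six]                     # (t, n_stations)
        noisy = vals + rng_obs.normal(0.0, pcfg.noise_sd, vals.shape)
        noisy = np.maximum(noisy, 0.0)
        n_t, n_s = noisy.shape
        frames.append(pd.DataFrame({
            "station_id": np.tile(stations["station_id"].to_numpy(), n_t),
            "lat": np.tile(stations["lat"].to_numpy(), n_t),
            "lon": np.tile(stations["lon"].to_numpy(), n_t),
            "date": np.repeat(all_dates.values, n_s),
            "pollutant": pol,
            "value": noisy.ravel(),
        }))
    observations = pd.concat(frames, ignore_index=True)

    return LatentScenario(
        config=config, grid=grid, years=sorted(config.years), dates=all_dates,
        truth=truth, counterfactual=counterfactual,
        region_masks=_default_region_masks(grid),
        population=population, elevation=elevation, landuse=landuse,
        population_density=population_density,
        baseline_rates=dict(config.baseline_rates),
        stations=stations, observations=observations, seed=seed,
    )


def synthesize_meteorology(scenario: LatentScenario, seed: int) -> xr.Dataset:
    """Generate the eight meteorological covariate fields for every scenario day.

    Variables listed in ``met.predictive_vars`` mix a per-cell-standardised
    copy of the anchor pollutant's truth with smooth noise at the configured
    correlation; the rest are pure smooth noise. With correlation 0 every
    variable is independent of the truth. The result is stored on the
    scenario (``scenario.meteorology``) and returned.
    """
    cfg = scenario.config.met
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    anchor_pol = cfg.anchor_pollutant if cfg.anchor_pollutant in scenario.truth \
        else sorted(scenario.truth)[0]
    anchor = scenario.truth[anchor_pol].values     # (t, ny, nx)
    mu, sd = anchor.mean(axis=0), anchor.std(axis=0)
    z = np.where(sd > 0, (anchor - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    n_t = anchor.shape[0]
    data = {}
    for var in MET_VARS:
        noise = np.stack([_smooth_field(rng, scenario.grid.shape, sigma_cells=3.0)
                          for _ in range(n_t)])
        nmu, nsd = noise.mean(axis=0), noise.std(axis=0)
        noise = np.where(nsd > 0, (noise - nmu) / np.where(nsd > 0, nsd, 1.0), noise)
        if var in cfg.predictive_vars and cfg.correlation != 0.0:
            rho = cfg.correlation
            mixed = rho * z + np.sqrt(1.0 - rho**2) * noise
        else:
            mixed = noise
        off, scale = _MET_SCALES[var]
        data[var] = (("time", "lat", "lon"), off + scale * mixed)

    ds = xr.Dataset(data, coords={"time": scenario.dates,
                                  "lat": scenario.grid.lat_centers,
                                  "lon": scenario.grid.lon_centers})
    scenario.meteorology = ds
    return ds


def _draw_qc(rng: np.random.Generator, shape: tuple[int, ...],
             qc: QCConfig) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """QC metadata with the configured fraction violating each threshold rule."""
    crf = rng.uniform(0.0, 0.5, shape)
    refl = rng.uniform(0.0, 30.0, shape)
    sza = rng.uniform(20.0, 85.0, shape)
    viol = {}
    for name, arr, lo, hi, frac in (
        ("crf", crf, 0.55, 1.0, qc.crf_fraction),
        ("refl", refl, 32.0, 90.0, qc.reflectivity_fraction),
        ("sza", sza, 85.5, 90.0, qc.sza_fraction),
    ):
        mask = rng.random(shape) < frac
        arr[mask] = rng.uniform(lo, hi, int(mask.sum()))
        viol[name] = mask
    anomaly = np.zeros(shape[-2:], dtype=bool)
    cols = [c for c in qc.row_anomaly_cols if 0 <= c < shape[-1]]
    anomaly[:, cols] = True
    contaminated = viol["crf"] | viol["refl"] | viol["sza"] | anomaly[None, :, :]
    meta = {"cloud_radiance_fraction": crf, "terrain_reflectivity": refl,
            "solar_zenith_angle": sza}
    return meta, anomaly, contaminated


def synthesize_satellite(scenario: LatentScenario, qc: QCConfig | None = None,
                         seed: int = 0,
                         pollutants: list[str] | None = None) -> dict[str, SatelliteSeries]:
    """Generate daily retrieval fields with controlled QC contamination.

    Pixels live on a grid ``pixel_factor`` times finer than the analysis grid;
    pixel value = gain * truth + offset + daily smooth bias + white noise.
    QC metadata is drawn so the configured fraction of pixels violates each
    threshold rule, and every pixel in the configured anomaly columns is
    flagged; the union of injected violations is recorded per pixel so filter
    tests have ground truth. Results are stored on ``scenario.satellite``.
    """
    qc = qc if qc is not None else scenario.config.qc
    pollutants = pollutants if pollutants is not None else sorted(scenario.truth)
    ss = np.random.SeedSequence(seed)
    out: dict[str, SatelliteSeries] = {}
    for sub, pol in zip(ss.spawn(len(pollutants)), sorted(pollutants)):
        pcfg = scenario.config.pollutants[pol]
        sat = pcfg.satellite
        rng = np.random.default_rng(sub)
        pixel_grid = scenario.grid.refine(sat.pixel_factor)
        cube = scenario.truth[pol].values
        f = sat.pixel_factor
        pix_truth = np.repeat(np.repeat(cube, f, axis=1), f, axis=2)
        n_t = pix_truth.shape[0]
        shape = (n_t,) + pixel_grid.shape
        bias = np.stack([sat.bias_sd * _smooth_field(rng, pixel_grid.shape, sigma_cells=6.0)
                         for _ in range(n_t)]) if sat.bias_sd > 0 else 0.0
        noise = rng.normal(0.0, sat.noise_sd, shape) if sat.noise_sd > 0 else 0.0
        values = sat.gain * pix_truth + sat.offset + bias + noise
        meta, anomaly, contaminated = _draw_qc(rng, shape, qc)
        out[pol] = SatelliteSeries(
            pollutant=pol, pixel_grid=pixel_grid, time=scenario.dates,
            values=values, row_anomaly=anomaly, contaminated=contaminated,
            **meta)
    scenario.satellite.update(out)
    return out
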