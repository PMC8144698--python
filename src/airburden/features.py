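"""Join station observations with co-located gridded covariates.

Each station-day becomes one training row carrying the observed concentration
(the target), the QC'd satellite covariate of the containing grid cell, the
eight meteorological covariates, static covariates (elevation, population
density, land-use class fractions), a day-of-window index, and the year
label. Stations are assigned to cells by the half-open interval convention
of :class:`~airburden.grid.GridSpec`; stations outside the grid are dropped
with a logged count.

Satellite gaps (cells where every contributing pixel was removed by QC on a
given day) are filled with the cell's window mean over the available days of
the same year, and flagged in a ``satellite_missing`` indicator column so the
model can learn to discount filled values.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec
from .synthetic import LANDUSE_CLASSES, MET_VARS

logger = logging.getLogger(__name__)

STATIC_COLUMNS = ["elevation", "population_density"] + [
    f"landuse_{cls}" for cls in LANDUSE_CLASSES]

#: stable column order of the feature table (documented contract for CSV I/O)
FEATURE_COLUMNS = (
    ["station_id", "date", "year", "day_of_window", "value",
     "satellite", "satellite_missing"]
    + list(MET_VARS) + STATIC_COLUMNS
)

#: columns offered to the regression model
PREDICTOR_COLUMNS = (["day_of_window", "satellite", "satellite_missing"]
                     + list(MET_VARS) + STATIC_COLUMNS)


def _gap_fill_satellite(sat: xr.DataArray) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing (time, lat, lon) satellite cells with per-year window means.

    Returns the filled cube and a boolean missing-indicator cube. Cells with
    no finite value in a whole year window fall back to that year's global
    mean, then to the all-year global mean.
    """
    vals = sat.values.astype(float).copy()
    missing = ~np.isfinite(vals)
    years = sat.time.dt.year.values
    overall = np.nanmean(vals) if np.isfinite(vals).any() else 0.0
    for y in np.unique(years):
        idx = years == y
        block = vals[idx]
        with np.errstate(invalid="ignore"):
            cell_mean = np.nanmean(block, axis=0)
        year_mean = np.nanmean(block) if np.isfinite(block).any() else overall
        cell_mean = np.where(np.isfinite(cell_mean), cell_mean, year_mean)
        block_missing = ~np.isfinite(block)
        block[block_missing] = np.broadcast_to(cell_mean, block.shape)[block_missing]
        vals[idx] = block
    return vals, missing


def build_table(observations: pd.DataFrame, satellite: xr.DataArray,
                meteorology: xr.Dataset, static: xr.Dataset,
                grid: GridSpec, pollutant: str,
                window_start: tuple[int, int] = (1, 23)) -> pd.DataFrame:
    """Build the model training table for one pollutant.

    Parameters
    ----------
    observations
        Long-format station observations with columns
        station_id, lat, lon, date, pollutant, value.
    satellite
        QC'd satellite covariate on (time, lat, lon); NaN marks QC gaps.
    meteorology
        Dataset with the eight meteorological variables on (time, lat, lon).
    static
        Dataset with elevation, population_density and land-use fractions.
    grid
        The analysis grid shared by all covariates.
    pollutant
        Which pollutant's rows to assemble.
    """
    obs = observations[observations["pollutant"] == pollutant].copy()
    if obs.empty:
        raise ValueError(f"no observations for pollutant {pollutant!r}")
    obs["date"] = pd.to_datetime(obs["date"])
    obs = obs.dropna(subset=["value"])

    inside = grid.contains(obs["lat"].to_numpy(), obs["lon"].to_numpy())
    n_dropped = int((~inside).sum())
    if n_dropped:
        n_stations = obs.loc[~inside, "station_id"].nunique()
        logger.warning("dropped %d station-day rows (%d stations) outside grid bounds",
                       n_dropped, n_stations)
    obs = obs.loc[inside]
    if obs.empty:
        raise ValueError("all stations fall outside the grid bounds")

    iy, ix = grid.cell_index(obs["lat"].to_numpy(), obs["lon"].to_numpy())
    time_index = pd.DatetimeIndex(satellite.time.values)
    pos = time_index.get_indexer(pd.DatetimeIndex(obs["date"]))
    if (pos < 0).any():
        missing_dates = sorted(set(obs.loc[pos < 0, "date"].dt.date))
        raise ValueError(f"observation dates missing from covariate calendar: {missing_dates[:5]}")

    sat_filled, sat_missing = _gap_fill_satellite(satellite)

    dates = pd.DatetimeIndex(obs["date"])
    start_per_row = pd.to_datetime({
        "year": dates.year,
        "month": window_start[0],
        "day": window_start[1]})
    table = pd.DataFrame({
        "station_id": obs["station_id"].to_numpy(),
        "date": dates,
        "year": dates.year,
        "day_of_window": (dates - pd.DatetimeIndex(start_per_row)).days + 1,
        "value": obs["value"].to_numpy(),
        "satellite": sat_filled[pos, iy, ix],
        "satellite_missing": sat_missing[pos, iy, ix].astype(float),
    })
    for var in MET_VARS:
        table[var] = meteorology[var].values[pos, iy, ix]
    for col in STATIC_COLUMNS:
        table[col] = static[col].values[iy, ix]
    return table[FEATURE_COLUMNS].reset_index(drop=True)


def build_cell_table(satellite: xr.DataArray, meteorology: xr.Dataset,
                     static: xr.Dataset, grid: GridSpec,
                     window_start: tuple[int, int] = (1, 23)) -> pd.DataFrame:
    """Covariate rows for every (day, grid cell), for full-grid prediction.

    Mirrors :func:`build_table`'s covariate construction (including the
    satellite gap-fill rule) without targets; rows are ordered by day then
    row-major cell index, with ``iy``/``ix`` columns for reshaping.
    """
    ny, nx = grid.shape
    time_index = pd.DatetimeIndex(satellite.time.values)
    n_t = len(time_index)
    sat_filled, sat_missing = _gap_fill_satellite(satellite)

    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    iy, ix = iy.ravel(), ix.ravel()
    start = pd.to_datetime({"year": time_index.year,
                            "month": window_start[0], "day": window_start[1]})
    dow = ((time_index - pd.DatetimeIndex(start)).days + 1).to_numpy()

    n_cells = ny * nx
    table = pd.DataFrame({
        "date": np.repeat(time_index.values, n_cells),
        "year": np.repeat(time_index.year.to_numpy(), n_cells),
        "day_of_window": np.repeat(dow, n_cells),
        "iy": np.tile(iy, n_t),
        "ix": np.tile(ix, n_t),
        "satellite": sat_filled[:, iy, ix].ravel(),
        "satellite_missing": sat_missing[:, iy, ix].astype(float).ravel(),
    })
    for var in MET_VARS:
        table[var] = meteorology[var].values[:, iy, ix].ravel()
    for col in STATIC_COLUMNS:
        table[col] = np.tile(static[col].values[iy, ix], n_t)
    return table


def to_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table with the documented stable column order."""
    out = table[FEATURE_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def from_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    table["date"] = pd.to_datetime(table["date"])
    return table[FEATURE_COLUMNS]
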