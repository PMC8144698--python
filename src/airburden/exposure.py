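"""Lockdown-versus-baseline exposure-change statistics.

Daily predicted concentration grids become: per-year window-mean grids, a
baseline grid (unweighted mean of the two baseline years' window means), a
percent-change grid 100 * (target - baseline) / baseline, regional percent
changes under area or population weighting, and weekly difference series in
consecutive 7-day bins from the window start. Negative values are decreases.

Calendar alignment: target and baseline days are paired on the
window-relative day index (1-based). In a leap target year the extra 69th
day has no baseline counterpart; it contributes to the target side of the
last weekly bin and to the target window mean, which matches comparing
calendar windows of unequal length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec

WEIGHTINGS = ("area", "population")


def window_mean(daily: xr.DataArray, allow_missing: bool = False) -> np.ndarray:
    """Per-cell arithmetic mean over the window days of a daily stack."""
    if daily.sizes.get("time", 0) == 0:
        raise ValueError("empty window: no days to average")
    vals = daily.values
    if not allow_missing and not np.all(np.isfinite(vals)):
        raise ValueError("missing days/cells present; pass allow_missing=True to skip them")
    return np.nanmean(vals, axis=0) if allow_missing else vals.mean(axis=0)


def _weights(grid: GridSpec, mask: np.ndarray | None, weighting: str,
             population: np.ndarray | None) -> np.ndarray:
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}, got {weighting!r}")
    if weighting == "population":
        if population is None:
            raise ValueError("population weighting requested but no population grid given")
        w = np.asarray(population, dtype=float)
    else:
        w = grid.cell_areas_km2
    if w.shape != grid.shape:
        raise ValueError("weight grid shape does not match analysis grid")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("region mask selects no cells")
        w = np.where(mask, w, 0.0)
    if w.sum() <= 0:
        raise ValueError("weights sum to zero over the masked region")
    return w


def _weighted_mean(field: np.ndarray, w: np.ndarray) -> float:
    return float((w * field).sum() / w.sum())


def percent_change(target_mean: np.ndarray,
                   baseline_means: tuple[np.ndarray, np.ndarray],
                   grid: GridSpec, mask: np.ndarray | None = None,
                   weighting: str = "area",
                   population: np.ndarray | None = None) -> float:
    """Regional percent change of the target window mean versus baseline.

    baseline = element-wise mean of the two baseline-year window means;
    returns 100 * (mean_w(target) - mean_w(baseline)) / mean_w(baseline)
    with mean_w area-weighted (default) or population-weighted.
    """
    baseline = 0.5 * (np.asarray(baseline_means[0], dtype=float)
                      + np.asarray(baseline_means[1], dtype=float))
    w = _weights(grid, mask, weighting, population)
    b = _weighted_mean(baseline, w)
    if b <= 0:
        raise ValueError(f"masked baseline mean must be positive, got {b}")
    t = _weighted_mean(np.asarray(target_mean, dtype=float), w)
    return 100.0 * (t - b) / b


def percent_change_grid(target_mean: np.ndarray,
                        baseline_means: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Cell-wise percent change; NaN where the baseline is not positive."""
    baseline = 0.5 * (np.asarray(baseline_means[0], dtype=float)
                      + np.asarray(baseline_means[1], dtype=float))
    target = np.asarray(target_mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (target - baseline) / baseline
    return np.where(baseline > 0, out, np.nan)


def weekly_bins(n_target_days: int, n_baseline_days: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Day-index pairs per 7-day bin from the window start; last bin may be short.

    Bins are laid out over the baseline day indices 1..n_baseline_days; target
    days beyond the baseline span (the leap-year day 69) join the final bin on
    the target side only.
    """
    if n_target_days < n_baseline_days:
        raise ValueError("target stack shorter than baseline stack")
    bins = []
    start = 0
    while start < n_baseline_days:
        stop = min(start + 7, n_baseline_days)
        t_stop = n_target_days if stop == n_baseline_days else stop
        bins.append((np.arange(start, t_stop), np.arange(start, stop)))
        start = stop
    return bins


def weekly_series(target_daily: xr.DataArray,
                  baseline_dailies: tuple[xr.DataArray, xr.DataArray],
                  grid: GridSpec, mask: np.ndarray | None = None,
                  weighting: str = "area",
                  population: np.ndarray | None = None) -> pd.DataFrame:
    """Per-week percent change of the target versus the two-year baseline.

    Both baseline stacks are paired with the target on the window-relative
    day index; each 7-day bin's percent change is
    100 * (mean(target, bin) - mean(baseline, bin)) / mean(baseline, bin)
    over the weighted masked region.
    """
    b1, b2 = baseline_dailies
    n_b = min(b1.sizes["time"], b2.sizes["time"])
    n_t = target_daily.sizes["time"]
    w = _weights(grid, mask, weighting, population)
    rows = []
    for week, (t_idx, b_idx) in enumerate(weekly_bins(n_t, n_b), start=1):
        if t_idx.size == 0 or b_idx.size == 0:
            raise ValueError(f"empty weekly bin {week}")
        t_mean = _weighted_mean(target_daily.values[t_idx].mean(axis=0), w)
        b_mean = _weighted_mean(
            0.5 * (b1.values[b_idx].mean(axis=0) + b2.values[b_idx].mean(axis=0)), w)
        if b_mean <= 0:
            raise ValueError(f"non-positive baseline mean in weekly bin {week}")
        rows.append({"week": week, "n_target_days": int(t_idx.size),
                     "n_baseline_days": int(b_idx.size),
                     "percent_change": 100.0 * (t_mean - b_mean) / b_mean})
    return pd.DataFrame(rows)


@dataclass
class ExposureSummary:
    """All change statistics for one pollutant."""

    pollutant: str
    year_means: dict[int, np.ndarray]
    baseline_mean: np.ndarray
    change_grid: np.ndarray
    regional: pd.DataFrame       # region, weighting, percent_change
    weekly: pd.DataFrame         # region, week, percent_change

    def to_dataset(self, grid: GridSpec) -> xr.Dataset:
        coords = {"lat": grid.lat_centers, "lon": grid.lon_centers}
        data = {f"window_mean_{y}": (("lat", "lon"), m)
                for y, m in self.year_means.items()}
        data["baseline_mean"] = (("lat", "lon"), self.baseline_mean)
        data["percent_change"] = (("lat", "lon"), self.change_grid)
        return xr.Dataset(data, coords=coords)


def summarize(pollutant: str, predicted: dict[int, xr.DataArray],
              target_year: int, grid: GridSpec,
              region_masks: dict[str, np.ndarray],
              population: np.ndarray | None = None,
              weighting: str = "area") -> ExposureSummary:
    """Window means, percent-change grid, regional and weekly statistics.

    ``predicted`` maps each year to its daily concentration stack; the two
    non-target years form the baseline.
    """
    baseline_years = sorted(y for y in predicted if y != target_year)
    if len(baseline_years) != 2:
        raise ValueError(f"expected exactly two baseline years, got {baseline_years}")
    year_means = {y: window_mean(da) for y, da in predicted.items()}
    b_means = (year_means[baseline_years[0]], year_means[baseline_years[1]])
    baseline = 0.5 * (b_means[0] + b_means[1])

    regional_rows = []
    weekly_frames = []
    for region, mask in region_masks.items():
        regional_rows.append({
            "region": region, "pollutant": pollutant, "weighting": weighting,
            "percent_change": percent_change(year_means[target_year], b_means,
                                             grid, mask, weighting, population)})
        wk = weekly_series(predicted[target_year],
                           (predicted[baseline_years[0]], predicted[baseline_years[1]]),
                           grid, mask, weighting, population)
        wk.insert(0, "region", region)
        wk.insert(1, "pollutant", pollutant)
        weekly_frames.append(wk)

    return ExposureSummary(
        pollutant=pollutant, year_means=year_means, baseline_mean=baseline,
        change_grid=percent_change_grid(year_means[target_year], b_means),
        regional=pd.DataFrame(regional_rows),
        weekly=pd.concat(weekly_frames, ignore_index=True),
    )
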