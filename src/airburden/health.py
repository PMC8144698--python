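"""Attributable premature mortality under a log-linear concentration-response model.

For a cause-specific annual baseline mortality rate y0, an exposure-response
coefficient ER (log relative risk per ug/m3), a no-risk threshold C0 and a
window-mean concentration C, the premature deaths attributed to exposure
above threshold in a cell with population Pop over a window of d days are

    M = y0 * d/365 * (1 - 1/exp[ER * max(C - C0, 0)]) * Pop.

1 - 1/RR is the attributable fraction; the max(., 0) truncation assigns zero
burden below threshold (C0: NO2 40 ug/m3, 8-h O3 100 ug/m3). Confidence
bounds come from substituting the ER interval endpoints, with concentration
and population treated as fixed. Region totals sum cells under a mask and
are therefore additive over disjoint masks.

The lockdown benefit is the difference between the mean burden of the two
baseline years and the target-year burden: positive values are avoided
deaths (benefit), negative values excess deaths (cost).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

MORTALITY_CAUSES = ("all_cause", "CVD", "RD", "COPD")
HEALTH_POLLUTANTS = ("NO2", "O3_8h")

#: default no-risk thresholds, ug/m3
DEFAULT_C0 = {"NO2": 40.0, "O3_8h": 100.0}


@dataclass(frozen=True)
class HealthParams:
    """Concentration-response parameters for one (cause, pollutant) pair.

    ER values are log relative risk per 1 ug/m3 unless ``er_units`` is
    ``"per_10"``, in which case they are divided by 10 on access (many
    epidemiological studies report excess risk per 10 ug/m3 increment).
    """

    cause: str
    pollutant: str
    ER_central: float
    ER_low: float
    ER_high: float
    C0: float
    y0_annual: float
    er_units: str = "per_1"

    def __post_init__(self) -> None:
        if self.cause not in MORTALITY_CAUSES:
            raise ValueError(f"unknown cause {self.cause!r}")
        if self.pollutant not in HEALTH_POLLUTANTS:
            raise ValueError(f"unsupported pollutant {self.pollutant!r}")
        if not (self.ER_low <= self.ER_central <= self.ER_high):
            raise ValueError("ER bounds must satisfy ER_low <= ER_central <= ER_high")
        if self.C0 <= 0:
            raise ValueError("threshold C0 must be positive")
        if not (0.0 < self.y0_annual < 1.0):
            raise ValueError("baseline annual mortality rate must lie in (0, 1)")
        if self.er_units not in ("per_1", "per_10"):
            raise ValueError("er_units must be 'per_1' or 'per_10'")

    @property
    def er_scale(self) -> float:
        return 0.1 if self.er_units == "per_10" else 1.0

    def er(self, which: str = "central") -> float:
        return {"central": self.ER_central, "low": self.ER_low,
                "high": self.ER_high}[which] * self.er_scale


@dataclass
class MortalityEstimate:
    """Deaths over the analysis window with ER-CI bounds."""

    cause: str
    pollutant: str
    region: str
    central: float
    low: float
    high: float

    def key(self) -> tuple[str, str, str]:
        return (self.pollutant, self.region, self.cause)


def _burden(C: np.ndarray, er: float, c0: float, y0_window: float,
            pop: np.ndarray, truncate: bool) -> float:
    excess = C - c0
    if truncate:
        excess = np.maximum(excess, 0.0)
    # evaluated as printed, 1 - 1/RR with RR = exp(ER * excess)
    m = y0_window * (1.0 - 1.0 / np.exp(er * excess)) * pop
    return float(m.sum())


def attributable_mortality(C: np.ndarray, params: HealthParams,
                           population: np.ndarray, window_days: int,
                           mask: np.ndarray | None = None,
                           region: str = "national",
                           truncate: bool = True) -> MortalityEstimate:
    """Window-total attributable deaths over a (masked) concentration grid.

    ``C`` is the window-mean concentration grid; the annual baseline rate is
    scaled by window_days/365. ``truncate=False`` keeps the raw formula,
    which yields negative cell contributions below threshold (provided for
    sensitivity; truncation is the default and standard practice).
    """
    C = np.asarray(C, dtype=float)
    pop = np.asarray(population, dtype=float)
    if C.shape != pop.shape:
        raise ValueError(f"concentration {C.shape} and population {pop.shape} grids differ")
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if np.any(C < 0):
        raise ValueError("negative concentrations")
    if np.any(pop < 0):
        raise ValueError("negative populations")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != C.shape:
            raise ValueError("mask shape does not match grids")
        pop = np.where(mask, pop, 0.0)
    y0_window = params.y0_annual * window_days / 365.0
    vals = {w: _burden(C, params.er(w), params.C0, y0_window, pop, truncate)
            for w in ("central", "low", "high")}
    return MortalityEstimate(cause=params.cause, pollutant=params.pollutant,
                             region=region, **vals)


def attributable_mortality_daily(daily: np.ndarray, params: HealthParams,
                                 population: np.ndarray,
                                 mask: np.ndarray | None = None,
                                 region: str = "national",
                                 truncate: bool = True) -> MortalityEstimate:
    """Day-wise sensitivity mode: apply the formula per day and sum.

    Each day contributes y0/365 of the annual baseline rate.
    """
    daily = np.asarray(daily, dtype=float)
    if daily.ndim != 3:
        raise ValueError("daily stack must be (time, lat, lon)")
    parts = [attributable_mortality(daily[i], params, population, 1, mask,
                                    region, truncate)
             for i in range(daily.shape[0])]
    return MortalityEstimate(
        cause=params.cause, pollutant=params.pollutant, region=region,
        central=sum(p.central for p in parts),
        low=sum(p.low for p in parts),
        high=sum(p.high for p in parts))


def lockdown_delta(baseline_pair: tuple[MortalityEstimate, MortalityEstimate],
                   target: MortalityEstimate) -> MortalityEstimate:
    """Benefit (positive, avoided deaths) or cost (negative) of the lockdown.

    delta = mean(baseline-year burdens) - target-year burden, applied to the
    central estimate and to each ER bound.
    """
    b1, b2 = baseline_pair
    for b in (b1, b2):
        if b.key() != target.key():
            raise ValueError(f"mismatched estimate keys: {b.key()} vs {target.key()}")
    return MortalityEstimate(
        cause=target.cause, pollutant=target.pollutant, region=target.region,
        central=0.5 * (b1.central + b2.central) - target.central,
        low=0.5 * (b1.low + b2.low) - target.low,
        high=0.5 * (b1.high + b2.high) - target.high)


def burden_table(estimates: list[MortalityEstimate]) -> pd.DataFrame:
    """Tabulate estimates as one row per (pollutant, region, cause).

    Causes overlap (all-cause subsumes the specific causes), so no totals row
    is added. The ``formatted`` column renders "central (low-high)".
    """
    columns = ["pollutant", "region", "cause", "central", "low", "high", "formatted"]
    rows = []
    for est in estimates:
        lo, hi = sorted((est.low, est.high))
        rows.append({
            "pollutant": est.pollutant, "region": est.region, "cause": est.cause,
            "central": est.central, "low": lo, "high": hi,
            "formatted": f"{est.central:.1f} ({lo:.1f}–{hi:.1f})"})
    return pd.DataFrame(rows, columns=columns)


def load_health_params(path: str | Path) -> list[HealthParams]:
    """Read concentration-response parameters from a YAML file.

    Expected layout: a top-level ``er_units`` (optional, default per_1) and a
    ``parameters`` list of mappings with keys cause, pollutant, ER_central,
    ER_low, ER_high, C0 (optional, defaults by pollutant) and y0_annual.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ValueError(f"health parameter file {path} lacks a 'parameters' list")
    units = doc.get("er_units", "per_1")
    out = []
    for entry in doc["parameters"]:
        entry = dict(entry)
        entry.setdefault("C0", DEFAULT_C0.get(entry.get("pollutant", ""), 0.0))
        entry.setdefault("er_units", units)
        out.append(HealthParams(**entry))
    return out


def assess(year_means: dict[int, np.ndarray], target_year: int,
           params: list[HealthParams], population: np.ndarray,
           window_days_by_year: dict[int, int],
           region_masks: dict[str, np.ndarray],
           truncate: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-year burdens and lockdown deltas for every (param, region) pair.

    Returns (per-year burden table, delta table).
    """
    baseline_years = sorted(y for y in year_means if y != target_year)
    if len(baseline_years) != 2:
        raise ValueError(f"expected exactly two baseline years, got {baseline_years}")
    per_year_rows: list[MortalityEstimate] = []
    deltas: list[MortalityEstimate] = []
    year_tags: list[int] = []
    for p in params:
        for region, mask in region_masks.items():
            by_year = {}
            for year, mean_grid in year_means.items():
                est = attributable_mortality(mean_grid, p, population,
                                             window_days_by_year[year], mask,
                                             region, truncate)
                by_year[year] = est
                per_year_rows.append(est)
                year_tags.append(year)
            deltas.append(lockdown_delta(
                (by_year[baseline_years[0]], by_year[baseline_years[1]]),
                by_year[target_year]))
    per_year = burden_table(per_year_rows)
    per_year.insert(3, "year", year_tags)
    return per_year, burden_table(deltas)
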