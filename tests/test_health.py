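"""Attributable-mortality accounting: closed-form oracle, thresholds, intervals."""

import numpy as np
import pandas as pd
import pytest

from airburden import health
from airburden.health import (HealthParams, MortalityEstimate,
                              attributable_mortality, burden_table,
                              load_health_params, lockdown_delta)
from airburden.pipeline import default_health_params_path


def params(cause="all_cause", pollutant="NO2", er=8e-4, lo=None, hi=None,
           c0=40.0, y0=0.006, units="per_1"):
    lo = er if lo is None else lo
    hi = er if hi is None else hi
    return HealthParams(cause=cause, pollutant=pollutant, ER_central=er,
                        ER_low=lo, ER_high=hi, C0=c0, y0_annual=y0,
                        er_units=units)


def test_single_cell_closed_form_oracle():
    """M = y0 * 69/365 * (1 - e^{-ER (C - C0)}) * Pop, evaluated independently."""
    C = np.array([[60.0]])
    pop = np.array([[1e6]])
    est = attributable_mortality(C, params(), pop, window_days=69)
    expected = 0.006 * (69 / 365) * (1 - np.exp(-8e-4 * 20.0)) * 1e6
    assert est.central == pytest.approx(expected, rel=1e-12)
    assert est.low == est.central == est.high


def test_threshold_identity_and_zero_population():
    pop = np.full((3, 3), 1e5)
    for pollutant, c0 in (("NO2", 40.0), ("O3_8h", 100.0)):
        for cause in health.MORTALITY_CAUSES:
            p = params(cause=cause, pollutant=pollutant, c0=c0)
            at = attributable_mortality(np.full((3, 3), c0), p, pop, 68)
            below = attributable_mortality(np.full((3, 3), c0 / 2), p, pop, 68)
            assert at.central == 0.0 and below.central == 0.0
    est = attributable_mortality(np.full((3, 3), 80.0), params(),
                                 np.zeros((3, 3)), 68)
    assert est.central == 0.0


def test_monotone_in_every_argument():
    rng = np.random.default_rng(0)
    for _ in range(50):
        C = rng.uniform(45, 120)
        er = rng.uniform(1e-4, 3e-3)
        pop = rng.uniform(1e3, 1e6)
        y0 = rng.uniform(1e-3, 1e-2)
        days = rng.integers(10, 69)
        base = attributable_mortality(
            np.array([[C]]), params(er=er, y0=y0), np.array([[pop]]), int(days)).central
        for dC, der, dpop, dy0, ddays in ((5, 0, 0, 0, 0), (0, 5e-4, 0, 0, 0),
                                          (0, 0, 1e4, 0, 0), (0, 0, 0, 1e-3, 0),
                                          (0, 0, 0, 0, 5)):
            bumped = attributable_mortality(
                np.array([[C + dC]]), params(er=er + der, y0=y0 + dy0),
                np.array([[pop + dpop]]), int(days + ddays)).central
            assert bumped >= base


def test_small_exposure_first_order_limit():
    """For x = ER (C - C0) <= 0.01, M is within 0.6% of y0_window * Pop * x."""
    rng = np.random.default_rng(1)
    for _ in range(200):
        er = rng.uniform(1e-5, 5e-4)
        excess = rng.uniform(0.1, 0.01 / er)
        x = er * excess
        assert x <= 0.01 + 1e-12
        y0, pop, days = rng.uniform(1e-3, 1e-2), rng.uniform(1e3, 1e6), 68
        est = attributable_mortality(np.array([[40.0 + excess]]),
                                     params(er=er, y0=y0),
                                     np.array([[pop]]), days)
        first_order = y0 * days / 365 * pop * x
        assert abs(est.central - first_order) / est.central <= 0.006


def test_interval_ordering_and_mask_additivity():
    rng = np.random.default_rng(2)
    C = rng.uniform(50, 120, (6, 6))   # supra-threshold everywhere
    pop = rng.uniform(1e3, 1e6, (6, 6))
    p = params(er=9e-4, lo=7e-4, hi=11e-4)
    left = np.zeros((6, 6), bool); left[:, :3] = True
    union = np.ones((6, 6), bool)
    est_union = attributable_mortality(C, p, pop, 69, union, "union")
    est_l = attributable_mortality(C, p, pop, 69, left, "left")
    est_r = attributable_mortality(C, p, pop, 69, ~left, "right")
    assert est_union.low <= est_union.central <= est_union.high
    for f in ("central", "low", "high"):
        assert getattr(est_union, f) == pytest.approx(
            getattr(est_l, f) + getattr(est_r, f), rel=1e-10)


def test_input_validation():
    pop = np.ones((2, 2))
    with pytest.raises(ValueError, match="negative concentrations"):
        attributable_mortality(np.full((2, 2), -1.0), params(), pop, 68)
    with pytest.raises(ValueError, match="grids differ"):
        attributable_mortality(np.ones((2, 3)), params(), pop, 68)
    with pytest.raises(ValueError, match="window_days"):
        attributable_mortality(np.ones((2, 2)), params(), pop, 0)
    with pytest.raises(ValueError, match="ER bounds"):
        params(er=1e-4, lo=2e-4, hi=3e-4)
    with pytest.raises(ValueError, match="mortality rate"):
        params(y0=1.5)
    with pytest.raises(ValueError, match="cause"):
        params(cause="mystery")


def test_truncation_flag_allows_negative_contributions():
    C = np.array([[20.0]])  # below threshold
    pop = np.array([[1e5]])
    trunc = attributable_mortality(C, params(), pop, 68, truncate=True)
    raw = attributable_mortality(C, params(), pop, 68, truncate=False)
    assert trunc.central == 0.0
    assert raw.central < 0.0


def test_daily_mode_matches_window_mode_for_constant_days():
    daily_stack = np.full((10, 2, 2), 70.0)
    pop = np.full((2, 2), 1e5)
    day_wise = health.attributable_mortality_daily(daily_stack, params(), pop)
    window = attributable_mortality(daily_stack[0], params(), pop, 10)
    assert day_wise.central == pytest.approx(window.central, rel=1e-12)


def make_est(c, lo, hi, **kw):
    base = dict(cause="all_cause", pollutant="NO2", region="national")
    base.update(kw)
    return MortalityEstimate(central=c, low=lo, high=hi, **base)


def test_lockdown_delta_arithmetic():
    target = make_est(90, 80, 100)
    delta = lockdown_delta((make_est(100, 90, 110), make_est(120, 110, 130)), target)
    assert delta.central == pytest.approx(20.0)
    assert delta.low == pytest.approx(20.0) and delta.high == pytest.approx(20.0)
    null = lockdown_delta((make_est(90, 80, 100), make_est(90, 80, 100)), target)
    assert null.central == 0.0
    with pytest.raises(ValueError, match="mismatched"):
        lockdown_delta((make_est(1, 0, 2, region="BTH"), make_est(1, 0, 2)), target)


def test_sign_straddling_er_interval_straddles_delta_sign():
    """ER_low < 0 < ER_high: the benefit interval changes sign, central stays +."""
    rng = np.random.default_rng(3)
    base_C = rng.uniform(105, 140, (5, 5))
    pop = rng.uniform(1e4, 1e6, (5, 5))
    p = params(pollutant="O3_8h", c0=100.0, er=4.7e-4, lo=-3e-4, hi=1.24e-3,
               cause="RD", y0=0.00068)
    target_C = 0.8 * base_C  # concentrations fell
    ests = {}
    for name, C in (("b1", base_C), ("b2", base_C), ("t", target_C)):
        ests[name] = attributable_mortality(C, p, pop, 69)
    delta = lockdown_delta((ests["b1"], ests["b2"]), ests["t"])
    assert delta.central > 0
    assert delta.low < 0 < delta.high


def test_burden_table_layout():
    empty = burden_table([])
    assert empty.empty and list(empty.columns) == [
        "pollutant", "region", "cause", "central", "low", "high", "formatted"]
    one = burden_table([make_est(12.3, 9.8, 14.7, region="toy-region")])
    assert len(one) == 1
    assert one.iloc[0]["formatted"] == "12.3 (9.8–14.7)"
    # additivity over disjoint sub-regions vs their union
    rows = burden_table([make_est(5, 4, 6, region="left"),
                         make_est(7, 6, 8, region="right"),
                         make_est(12, 10, 14, region="union")])
    sub = rows[rows["region"].isin(["left", "right"])]
    uni = rows[rows["region"] == "union"].iloc[0]
    for col in ("central", "low", "high"):
        assert uni[col] == pytest.approx(sub[col].sum(), rel=1e-10)


def test_packaged_parameter_file_loads_with_per10_scaling():
    plist = load_health_params(default_health_params_path())
    assert {p.pollutant for p in plist} == {"NO2", "O3_8h"}
    assert {p.cause for p in plist} == set(health.MORTALITY_CAUSES)
    no2_all = next(p for p in plist if p.pollutant == "NO2" and p.cause == "all_cause")
    assert no2_all.C0 == 40.0
    assert no2_all.er("central") == pytest.approx(no2_all.ER_central / 10)
    o3 = [p for p in plist if p.pollutant == "O3_8h"]
    assert any(p.ER_low < 0 < p.ER_high for p in o3)
    assert all(p.C0 == 100.0 for p in o3)


def test_assess_builds_per_year_and_delta_tables():
    years = {2018: np.full((3, 3), 80.0), 2019: np.full((3, 3), 76.0),
             2020: np.full((3, 3), 60.0)}
    pop = np.full((3, 3), 1e5)
    masks = {"national": np.ones((3, 3), bool)}
    per_year, deltas = health.assess(years, 2020, [params()], pop,
                                     {2018: 68, 2019: 68, 2020: 69}, masks)
    assert len(per_year) == 3 and len(deltas) == 1
    assert deltas.iloc[0]["central"] > 0  # concentrations fell -> benefit
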