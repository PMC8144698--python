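"""QC filtering against a brute-force oracle; regridding against polygon overlap."""

import numpy as np
import pytest
from shapely.geometry import box

from airburden.grid import GridSpec, area_weighted_mean
from airburden.satellite_qc import (RetrievalField, filter_retrievals,
                                    regrid_area_weighted)


def make_field(rng, ny=20, nx=20, lat0=30.0, lon0=110.0, res=0.25,
               crf=None, refl=None, sza=None, anomaly=None, values=None):
    shape = (ny, nx)
    return RetrievalField(
        values=values if values is not None else rng.normal(10, 3, shape),
        cloud_radiance_fraction=crf if crf is not None else rng.uniform(0, 1, shape),
        terrain_reflectivity=refl if refl is not None else rng.uniform(0, 60, shape),
        solar_zenith_angle=sza if sza is not None else rng.uniform(20, 90, shape),
        row_anomaly=anomaly if anomaly is not None else rng.random(shape) < 0.05,
        lat_edges=lat0 + res * np.arange(ny + 1),
        lon_edges=lon0 + res * np.arange(nx + 1),
    )


def brute_force_retained(field):
    """Independent pixel-by-pixel scan of the four QC rules."""
    ny, nx = field.values.shape
    keep = np.zeros((ny, nx), dtype=bool)
    for i in range(ny):
        for j in range(nx):
            bad = (field.cloud_radiance_fraction[i, j] > 0.5
                   or field.terrain_reflectivity[i, j] > 30.0
                   or field.solar_zenith_angle[i, j] > 85.0
                   or field.row_anomaly[i, j])
            keep[i, j] = not bad
    return keep


def test_single_pixel_rule_examples():
    rng = np.random.default_rng(0)
    ones = np.ones((1, 1))
    removed = make_field(rng, 1, 1, crf=0.6 * ones, refl=10 * ones, sza=40 * ones,
                         anomaly=np.zeros((1, 1), bool), values=5 * ones)
    res = filter_retrievals(removed)
    assert np.isnan(res.field.values[0, 0])
    assert res.removed_per_rule["cloud_radiance_fraction"] == 1
    assert res.removed_total == 1


def test_boundary_values_are_retained():
    """crf=0.5, reflectivity=30%, sza=85 sit on the strict-inequality thresholds."""
    ones = np.ones((1, 1))
    field = make_field(np.random.default_rng(0), 1, 1, crf=0.5 * ones,
                       refl=30.0 * ones, sza=85.0 * ones,
                       anomaly=np.zeros((1, 1), bool), values=7 * ones)
    res = filter_retrievals(field)
    assert res.field.values[0, 0] == 7
    assert res.removed_total == 0


def test_filter_matches_brute_force_scan():
    rng = np.random.default_rng(42)
    field = make_field(rng, 100, 100)  # 1e4 random pixels
    res = filter_retrievals(field)
    keep_oracle = brute_force_retained(field)
    assert np.array_equal(np.isfinite(res.field.values), keep_oracle)


def test_filter_is_idempotent():
    rng = np.random.default_rng(1)
    field = make_field(rng, 30, 30)
    once = filter_retrievals(field)
    twice = filter_retrievals(once.field)
    assert np.array_equal(np.isnan(once.field.values), np.isnan(twice.field.values))
    assert np.array_equal(
        once.field.values[np.isfinite(once.field.values)],
        twice.field.values[np.isfinite(twice.field.values)])
    assert twice.removed_total == 0


def test_adding_a_violation_never_increases_retained_count():
    rng = np.random.default_rng(2)
    field = make_field(rng, 15, 15)
    base_retained = np.isfinite(filter_retrievals(field).field.values).sum()
    for _ in range(20):
        i, j = rng.integers(0, 15, 2)
        worse = make_field(rng, 15, 15, crf=field.cloud_radiance_fraction.copy(),
                           refl=field.terrain_reflectivity.copy(),
                           sza=field.solar_zenith_angle.copy(),
                           anomaly=field.row_anomaly.copy(),
                           values=field.values.copy())
        worse.cloud_radiance_fraction[i, j] = 0.9
        retained = np.isfinite(filter_retrievals(worse).field.values).sum()
        assert retained <= base_retained


def test_missing_qc_metadata_is_rejected():
    rng = np.random.default_rng(3)
    field = make_field(rng, 5, 5)
    field.cloud_radiance_fraction[2, 2] = np.nan
    with pytest.raises(ValueError, match="metadata"):
        filter_retrievals(field)


def clean_field(values, lat0=30.0, lon0=110.0, res=0.25):
    ny, nx = values.shape
    rng = np.random.default_rng(0)
    return make_field(rng, ny, nx, lat0=lat0, lon0=lon0, res=res,
                      crf=np.zeros((ny, nx)), refl=np.zeros((ny, nx)),
                      sza=np.full((ny, nx), 40.0),
                      anomaly=np.zeros((ny, nx), bool), values=values)


def test_uniform_field_regrids_to_itself():
    target = GridSpec(30, 32, 110, 112, 0.5)
    field = clean_field(np.full((16, 16), 3.25), res=0.125)
    out = regrid_area_weighted(field, target)
    assert np.allclose(out, 3.25, rtol=0, atol=1e-12)


def test_two_equal_area_pixels_average_symmetrically():
    target = GridSpec(30, 30.5, 110, 110.5, 0.5)  # one cell
    field = clean_field(np.array([[1.0, 3.0]]), res=0.25)
    field.lat_edges = np.array([30.0, 30.5])
    out = regrid_area_weighted(field, target)
    assert out[0, 0] == pytest.approx(2.0, rel=1e-14)


def test_regrid_matches_polygon_overlap_oracle():
    """Random offset pixel mosaic vs shapely box intersections in (lon, sin lat)."""
    rng = np.random.default_rng(7)
    target = GridSpec(30, 32, 110, 112, 0.5)
    ny, nx = 11, 13
    lat_edges = np.sort(rng.uniform(29.7, 32.3, ny + 1))
    lon_edges = np.sort(rng.uniform(109.7, 112.3, nx + 1))
    lat_edges += np.linspace(0, 1e-3, ny + 1)  # guard strict monotonicity
    lon_edges += np.linspace(0, 1e-3, nx + 1)
    values = rng.normal(20, 5, (ny, nx))
    values[rng.random((ny, nx)) < 0.15] = np.nan  # holes
    field = clean_field(np.ones((ny, nx)))
    field.values = values
    field.lat_edges, field.lon_edges = lat_edges, lon_edges
    out = regrid_area_weighted(field, target)

    sin = lambda d: np.sin(np.radians(d))
    for a in range(target.n_lat):
        for b in range(target.n_lon):
            cell = box(target.lon_edges[b], sin(target.lat_edges[a]),
                       target.lon_edges[b + 1], sin(target.lat_edges[a + 1]))
            num = den = 0.0
            for i in range(ny):
                for j in range(nx):
                    if not np.isfinite(values[i, j]):
                        continue
                    pix = box(lon_edges[j], sin(lat_edges[i]),
                              lon_edges[j + 1], sin(lat_edges[i + 1]))
                    w = cell.intersection(pix).area
                    num += w * values[i, j]
                    den += w
            if den == 0:
                assert np.isnan(out[a, b])
            else:
                assert out[a, b] == pytest.approx(num / den, rel=1e-10)


def test_regrid_conserves_global_area_weighted_mean():
    """Complete coverage, nothing missing: the global mean is preserved."""
    rng = np.random.default_rng(8)
    target = GridSpec(30, 34, 110, 114, 0.5)
    pixel_grid = target.refine(3)
    values = rng.normal(15, 4, pixel_grid.shape)
    field = clean_field(values)
    field.lat_edges = pixel_grid.lat_edges
    field.lon_edges = pixel_grid.lon_edges
    out = regrid_area_weighted(field, target)
    mean_src = area_weighted_mean(values, pixel_grid)
    mean_dst = area_weighted_mean(out, target)
    assert mean_dst == pytest.approx(mean_src, rel=1e-10)


def test_degenerate_pixels_rejected():
    field = clean_field(np.ones((2, 2)))
    field.lat_edges = np.array([30.0, 30.0, 30.5])  # zero-height pixel row
    with pytest.raises(ValueError, match="degenerate"):
        regrid_area_weighted(field, GridSpec(30, 31, 110, 111, 0.5))
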