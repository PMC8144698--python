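"""Satellite retrieval quality control and area-weighted regridding.

Level-3-style retrieval fields carry per-pixel quality metadata. Pixels are
discarded when any of four rules fires:

* cloud radiance fraction > 0.5,
* terrain reflectivity > 30 %,
* solar zenith angle > 85 degrees,
* the pixel sits in a cross-track column affected by the row anomaly.

All thresholds are strict inequalities, so boundary values (0.5, 30, 85) are
retained. Removed pixels become missing (NaN), never zero — zero is a valid
retrieval. Surviving pixels are resampled to the analysis grid with an
area-weighted average over the exact spherical overlap of axis-aligned
pixel rectangles with target cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import GridSpec

CRF_MAX = 0.5          # cloud radiance fraction, unitless
REFLECTIVITY_MAX = 30.0  # terrain reflectivity, percent
SZA_MAX = 85.0         # solar zenith angle, degrees

QC_RULES = ("cloud_radiance_fraction", "terrain_reflectivity",
            "solar_zenith_angle", "row_anomaly")


@dataclass
class RetrievalField:
    """One day of satellite pixels with per-pixel QC metadata.

    ``values`` holds the retrieval (column density or mixing ratio, product
    units) with NaN for missing pixels. Pixel geometry is an axis-aligned
    rectangular mosaic given by edge vectors (``lat_edges`` has
    ``values.shape[0] + 1`` entries).
    """

    values: np.ndarray
    cloud_radiance_fraction: np.ndarray
    terrain_reflectivity: np.ndarray
    solar_zenith_angle: np.ndarray
    row_anomaly: np.ndarray
    lat_edges: np.ndarray
    lon_edges: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        shape = self.values.shape
        if len(shape) != 2:
            raise ValueError("retrieval values must be 2-D (lat, lon)")
        for name in ("cloud_radiance_fraction", "terrain_reflectivity",
                     "solar_zenith_angle", "row_anomaly"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"QC field {name} shape {arr.shape} != values shape {shape}")
            setattr(self, name, arr)
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        if self.lat_edges.size != shape[0] + 1 or self.lon_edges.size != shape[1] + 1:
            raise ValueError("pixel edge vectors inconsistent with values shape")


@dataclass
class FilterResult:
    field: RetrievalField
    removed_per_rule: dict[str, int]
    removed_total: int


def _violations(field: RetrievalField) -> dict[str, np.ndarray]:
    crf = np.asarray(field.cloud_radiance_fraction, dtype=float)
    refl = np.asarray(field.terrain_reflectivity, dtype=float)
    sza = np.asarray(field.solar_zenith_angle, dtype=float)
    for name, arr in (("cloud_radiance_fraction", crf),
                      ("terrain_reflectivity", refl),
                      ("solar_zenith_angle", sza)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"QC metadata '{name}' contains missing values; refusing to filter")
    return {
        "cloud_radiance_fraction": crf > CRF_MAX,
        "terrain_reflectivity": refl > REFLECTIVITY_MAX,
        "solar_zenith_angle": sza > SZA_MAX,
        "row_anomaly": np.asarray(field.row_anomaly, dtype=bool),
    }


def filter_retrievals(field: RetrievalField) -> FilterResult:
    """Mask pixels violating any QC rule; report removals per rule.

    A pixel violating several rules is counted once under each rule it
    violates but removed once. Counts refer to pixels that carried a finite
    value before this call, which makes filtering idempotent in both the
    field and the bookkeeping.
    """
    viol = _violations(field)
    finite = np.isfinite(field.values)
    removed = {rule: int((v & finite).sum()) for rule, v in viol.items()}
    any_viol = np.logical_or.reduce(list(viol.values()))
    out = np.where(any_viol, np.nan, field.values)
    return FilterResult(
        field=replace(field, values=out),
        removed_per_rule=removed,
        removed_total=int((any_viol & finite).sum()),
    )


def _overlap_matrix(target_edges: np.ndarray, source_edges: np.ndarray,
                    spherical: bool) -> np.ndarray:
    """(n_target, n_source) interval-overlap lengths.

    For latitude, lengths are measured in sin(lat) so that the product of the
    two 1-D overlaps is proportional to spherical area.
    """
    t_lo, t_hi = target_edges[:-1, None], target_edges[1:, None]
    s_lo, s_hi = source_edges[None, :-1], source_edges[None, 1:]
    lo = np.maximum(t_lo, s_lo)
    hi = np.minimum(t_hi, s_hi)
    if spherical:
        lo, hi = np.sin(np.radians(lo)), np.sin(np.radians(hi))
    return np.maximum(hi - lo, 0.0)


def regrid_area_weighted(field: RetrievalField, target: GridSpec) -> np.ndarray:
    """Resample a pixel mosaic to the target grid by area-weighted average.

    Each target cell is the overlap-area-weighted mean of contributing
    non-missing pixels; cells with zero contributing area come back NaN.
    """
    for name, edges in (("lat", field.lat_edges), ("lon", field.lon_edges)):
        if np.any(np.diff(edges) <= 0):
            raise ValueError(f"degenerate pixel geometry: non-increasing {name} edges")
    w_lat = _overlap_matrix(target.lat_edges, field.lat_edges, spherical=True)
    w_lon = _overlap_matrix(target.lon_edges, field.lon_edges, spherical=False)
    finite = np.isfinite(field.values)
    vals = np.where(finite, field.values, 0.0)
    num = w_lat @ vals @ w_lon.T
    den = w_lat @ finite.astype(float) @ w_lon.T
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out
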