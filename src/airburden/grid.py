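"""Regular latitude/longitude analysis grids.

All gridded fields in the pipeline live on a :class:`GridSpec`: a regular
lat/lon grid addressed row-major by (lat index, lon index), with coordinates
referring to cell centers. Cell areas are latitude-dependent and computed on
the sphere, so area-weighted statistics are exact for rectangular cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid of square (in degrees) cells.

    Parameters
    ----------
    lat_min, lat_max, lon_min, lon_max
        Grid bounds in degrees. Bounds refer to outer cell edges.
    resolution
        Cell size in degrees (default 0.25).
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = 0.25

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"grid resolution must be positive, got {self.resolution}")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("grid bounds must satisfy lat_max > lat_min and lon_max > lon_min")
        for extent, name in ((self.lat_max - self.lat_min, "lat"), (self.lon_max - self.lon_min, "lon")):
            n = extent / self.resolution
            if abs(n - round(n)) > 1e-6:
                raise ValueError(f"{name} extent {extent} is not a multiple of resolution {self.resolution}")

    @property
    def n_lat(self) -> int:
        return round((self.lat_max - self.lat_min) / self.resolution)

    @property
    def n_lon(self) -> int:
        return round((self.lon_max - self.lon_min) / self.resolution)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def lat_edges(self) -> np.ndarray:
        return self.lat_min + self.resolution * np.arange(self.n_lat + 1)

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon_min + self.resolution * np.arange(self.n_lon + 1)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + self.resolution * (np.arange(self.n_lat) + 0.5)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.resolution * (np.arange(self.n_lon) + 0.5)

    @property
    def cell_areas_km2(self) -> np.ndarray:
        """(n_lat, n_lon) array of spherical cell areas in km^2 (all > 0)."""
        edges = np.radians(self.lat_edges)
        band = EARTH_RADIUS_KM**2 * np.radians(self.resolution) * np.diff(np.sin(edges))
        return np.repeat(band[:, None], self.n_lon, axis=1)

    def refine(self, factor: int) -> "GridSpec":
        """Return a grid with the same bounds at ``resolution / factor``."""
        if factor < 1:
            raise ValueError("refinement factor must be >= 1")
        return GridSpec(self.lat_min, self.lat_max, self.lon_min, self.lon_max,
                        self.resolution / factor)

    def contains(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """Vectorised point-in-grid test under half-open cell intervals.

        A point belongs to the grid iff it falls in some cell's half-open
        interval [edge, edge + resolution), so points exactly on the upper
        outer boundary are outside.
        """
        lat = np.asarray(lat)
        lon = np.asarray(lon)
        return ((lat >= self.lat_min) & (lat < self.lat_max)
                & (lon >= self.lon_min) & (lon < self.lon_max))

    def cell_index(self, lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (lat index, lon index) of the containing cell.

        Uses the half-open convention [edge, edge + resolution): a point on an
        interior edge belongs to the cell starting at that edge. Raises for
        points outside the grid; callers that may hold out-of-bounds points
        should mask with :meth:`contains` first.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        if not np.all(self.contains(lat, lon)):
            raise ValueError("coordinates outside grid bounds")
        iy = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        ix = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        # guard against float round-off right at the upper boundary
        iy = np.clip(iy, 0, self.n_lat - 1)
        ix = np.clip(ix, 0, self.n_lon - 1)
        return iy, ix


def area_weighted_mean(field: np.ndarray, grid: GridSpec,
                       mask: np.ndarray | None = None) -> float:
    """Area-weighted mean of a 2-D field over an optional boolean mask."""
    field = np.asarray(field, dtype=float)
    if field.shape != grid.shape:
        raise ValueError(f"field shape {field.shape} does not match grid {grid.shape}")
    w = grid.cell_areas_km2
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask selects no cells")
        w = np.where(mask, w, 0.0)
    finite = np.isfinite(field)
    w = np.where(finite, w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("no finite cells under mask")
    return float((w * np.where(finite, field, 0.0)).sum() / total)
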