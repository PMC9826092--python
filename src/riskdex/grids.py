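"""Raster grid containers.

All spatial products in the pipeline live on one shared geographic grid:
north-up, cell-centre registered, row 0 = northernmost row, WGS84 decimal
degrees.  Area quantities downstream are pixel counts on this grid, so the
only geometry a layer needs is its :class:`GridSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WGS84 = "EPSG:4326"

EARTH_RADIUS_KM = 6371.0088


class GridMismatchError(ValueError):
    """Two rasters do not share the same grid."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up geographic raster.

    Parameters
    ----------
    lon_min, lat_max
        Western and northern *edges* of the grid in decimal degrees.
    resolution
        Cell size in degrees (square cells).
    n_rows, n_cols
        Grid shape; row 0 is the northernmost row.
    crs
        Coordinate reference system identifier (WGS84 throughout).
    """

    lon_min: float
    lat_max: float
    resolution: float
    n_rows: int
    n_cols: int
    crs: str = WGS84

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @classmethod
    def from_extent(
        cls,
        lon_min: float,
        lon_max: float,
        lat_min: float,
        lat_max: float,
        resolution: float,
    ) -> "GridSpec":
        if not (lon_max > lon_min and lat_max > lat_min):
            raise ValueError("degenerate extent")
        n_cols = int(round((lon_max - lon_min) / resolution))
        n_rows = int(round((lat_max - lat_min) / resolution))
        if n_cols < 1 or n_rows < 1:
            raise ValueError("extent smaller than one cell")
        return cls(lon_min, lat_max, resolution, n_rows, n_cols)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.resolution

    @property
    def lat_min(self) -> float:
        return self.lat_max - self.n_rows * self.resolution

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-D arrays of cell-centre coordinates."""
        lon = self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution
        lat = self.lat_max - (np.arange(self.n_rows) + 0.5) * self.resolution
        return np.meshgrid(lon, lat)

    def index_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point; points outside raise."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        row = np.floor((self.lat_max - lat) / self.resolution).astype(int)
        # points exactly on the east/south edge belong to the last cell
        col = np.where((lon == self.lon_max), self.n_cols - 1, col)
        row = np.where((lat == self.lat_min), self.n_rows - 1, row)
        if np.any((col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)):
            raise ValueError("point outside grid extent")
        return row, col


def check_same_grid(*specs: GridSpec) -> GridSpec:
    first = specs[0]
    for other in specs[1:]:
        if other != first:
            raise GridMismatchError(f"grids differ: {first} vs {other}")
    return first


@dataclass
class RasterGrid:
    """One 2-D layer bound to a :class:`GridSpec`."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise GridMismatchError(
                f"array shape {self.values.shape} != grid shape {self.spec.shape}"
            )

    def aligned_with(self, other: "RasterGrid") -> bool:
        return self.spec == other.spec

    def sample(self, lon, lat) -> np.ndarray:
        row, col = self.spec.index_of(lon, lat)
        return self.values[row, col]


@dataclass
class ClimateStack:
    """Named continuous layers (climate variables) on one grid."""

    spec: GridSpec
    variables: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.variables.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.spec.shape:
                raise GridMismatchError(f"variable {name!r} shape mismatch")
            self.variables[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.variables)

    def layer(self, name: str) -> RasterGrid:
        return RasterGrid(self.spec, self.variables[name])

    def sample(self, lon, lat, names: list[str] | None = None) -> np.ndarray:
        """Feature matrix (n_points, n_vars) sampled at point locations."""
        row, col = self.spec.index_of(lon, lat)
        names = names if names is not None else self.names
        return np.column_stack([self.variables[n][row, col] for n in names])

    def as_array(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.names
        return np.stack([self.variables[n] for n in names])

    def subset(self, names: list[str]) -> "ClimateStack":
        return ClimateStack(self.spec, {n: self.variables[n] for n in names})


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_haversine_km(points: np.ndarray) -> np.ndarray:
    """Full symmetric distance matrix for an (n, 2) lon/lat array."""
    pts = np.asarray(points, dtype=float)
    lon = pts[:, 0][:, None]
    lat = pts[:, 1][:, None]
    return haversine_km(lon, lat, lon.T, lat.T)
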