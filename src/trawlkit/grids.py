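"""Equal-area gridding of sampling events.

Two grid backends:

* :class:`HexGrid` — a regular planar hexagonal tessellation on a spherical
  Lambert azimuthal equal-area (LAEA) projection centred on the survey
  domain.  The per-cell area is pinned to the mean cell area of the
  aperture-3 icosahedral hexagonal global grid at the same resolution,
  A(r) = S_earth / (10·3^r + 2) with S_earth = 4π·(6371.0088 km)², i.e.
  ≈ 23,320 km² at resolution 7 and ≈ 7,774 km² at resolution 8.  Because the
  projection is exactly equal-area on the sphere, planar binning preserves
  the cell-area semantics of the icosahedral grid over regional survey
  domains without its spherical geometry; the backend is pluggable for a
  true discrete global grid.

* :class:`BioTimeGrid` — the 5×5 rectangular latitude/longitude grid whose
  cell size is 1/5 of the survey's latitudinal and longitudinal range, used
  by the BioTIME-style footprint rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .errors import DomainError

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius
EARTH_SURFACE_KM2 = 4.0 * math.pi * EARTH_RADIUS_KM**2


def hex_cell_area_km2(resolution: int) -> float:
    """Mean cell area of the aperture-3 icosahedral hex grid at a resolution.

    The grid has 10·3^r + 2 cells covering the Earth's surface; areas shrink
    by a factor 3 per resolution step.
    """
    if resolution < 0:
        raise DomainError("resolution must be non-negative")
    return EARTH_SURFACE_KM2 / (10 * 3**resolution + 2)


# -- spherical Lambert azimuthal equal-area projection -----------------------

def laea_forward(lat, lon, lat0: float, lon0: float):
    """Project WGS84 degrees to LAEA plane km, centred at (lat0, lon0)."""
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    phi0, lam0 = math.radians(lat0), math.radians(lon0)
    dlam = lon - lam0
    cosc = np.sin(phi0) * np.sin(lat) + np.cos(phi0) * np.cos(lat) * np.cos(dlam)
    k = np.sqrt(2.0 / np.clip(1.0 + cosc, 1e-12, None))
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(dlam)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(lat) - np.sin(phi0) * np.cos(lat) * np.cos(dlam)
    )
    return x, y


def laea_inverse(x, y, lat0: float, lon0: float):
    """Inverse of :func:`laea_forward`; returns (lat, lon) in degrees."""
    x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
    y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
    phi0, lam0 = math.radians(lat0), math.radians(lon0)
    rho = np.sqrt(x**2 + y**2)
    c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        lat = np.where(
            rho == 0,
            phi0,
            np.arcsin(
                np.cos(c) * np.sin(phi0)
                + np.where(rho == 0, 0.0, y * np.sin(c) * np.cos(phi0) / np.where(rho == 0, 1.0, rho))
            ),
        )
        lon = lam0 + np.arctan2(
            x * np.sin(c),
            rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
        )
        lon = np.where(rho == 0, lam0, lon)
    return np.degrees(lat), np.degrees(lon)


# -- hexagonal tessellation ---------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Descriptor of a grid backend for provenance/logging."""

    kind: str  # "equal_area_hex" or "biotime_rect"
    resolution: int | None
    cell_area_km2: float | None
    center: tuple[float, float] | None


class HexGrid:
    """Pointy-top hexagonal tessellation on an LAEA plane.

    Cells are addressed by axial coordinates ``"q|r"``.  The tessellation is
    anchored so that axial (0, 0) is centred on the projection origin, making
    cell assignment deterministic given the projection centre.
    """

    def __init__(self, center_lat: float, center_lon: float, resolution: int):
        self.center_lat = float(center_lat)
        self.center_lon = float(center_lon)
        self.resolution = int(resolution)
        self.cell_area_km2 = hex_cell_area_km2(resolution)
        # hexagon area = (3*sqrt(3)/2) * side^2
        self.side_km = math.sqrt(2.0 * self.cell_area_km2 / (3.0 * math.sqrt(3.0)))

    @classmethod
    def for_extent(
        cls, latitudes, longitudes, resolution: int
    ) -> "HexGrid":
        """Grid centred on the midpoint of the coordinate extent."""
        lat = np.asarray(latitudes, dtype=float)
        lon = np.asarray(longitudes, dtype=float)
        return cls(
            (lat.min() + lat.max()) / 2.0, (lon.min() + lon.max()) / 2.0, resolution
        )

    @property
    def spec(self) -> GridSpec:
        return GridSpec(
            "equal_area_hex",
            self.resolution,
            self.cell_area_km2,
            (self.center_lat, self.center_lon),
        )

    # axial <-> plane (pointy-top): see Amit Patel's hex-grid notes
    def _plane_to_axial(self, x, y):
        s = self.side_km
        q = (math.sqrt(3.0) / 3.0 * x - y / 3.0) / s
        r = (2.0 / 3.0 * y) / s
        return q, r

    def _axial_to_plane(self, q, r):
        s = self.side_km
        x = s * math.sqrt(3.0) * (np.asarray(q, float) + np.asarray(r, float) / 2.0)
        y = s * 1.5 * np.asarray(r, float)
        return x, y

    @staticmethod
    def _axial_round(q, r):
        """Cube-coordinate rounding to the nearest hexagon centre."""
        x = np.asarray(q, dtype=float)
        z = np.asarray(r, dtype=float)
        y = -x - z
        rx, ry, rz = np.round(x), np.round(y), np.round(z)
        dx, dy, dz = np.abs(rx - x), np.abs(ry - y), np.abs(rz - z)
        fix_x = (dx > dy) & (dx > dz)
        fix_z = ~fix_x & (dz > dy)
        rx = np.where(fix_x, -ry - rz, rx)
        rz = np.where(fix_z, -rx - ry, rz)
        return rx.astype(int), rz.astype(int)

    def assign(self, lat, lon) -> np.ndarray:
        """Cell id ("q|r") for each coordinate pair."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        if np.any(np.abs(lat) > 90):
            raise DomainError("latitude outside [-90, 90]")
        x, y = laea_forward(lat, lon, self.center_lat, self.center_lon)
        q, r = self._plane_to_axial(x, y)
        qi, ri = self._axial_round(q, r)
        return np.char.add(np.char.add(qi.astype(str), "|"), ri.astype(str))

    @staticmethod
    def parse_cell(cell_id: str) -> tuple[int, int]:
        q, r = cell_id.split("|")
        return int(q), int(r)

    def centroid(self, cell_id: str) -> tuple[float, float]:
        """(lat, lon) of a cell centre."""
        q, r = self.parse_cell(cell_id)
        x, y = self._axial_to_plane(q, r)
        lat, lon = laea_inverse(x, y, self.center_lat, self.center_lon)
        return float(lat), float(lon)

    def polygon(self, cell_id: str, planar: bool = False) -> shapely.Polygon:
        """Hexagon outline of a cell, in lon/lat degrees (or LAEA km)."""
        q, r = self.parse_cell(cell_id)
        cx, cy = self._axial_to_plane(q, r)
        angles = np.radians(np.arange(6) * 60.0 + 30.0)  # pointy-top vertices
        vx = cx + self.side_km * np.cos(angles)
        vy = cy + self.side_km * np.sin(angles)
        if planar:
            return shapely.Polygon(zip(vx, vy))
        lat, lon = laea_inverse(vx, vy, self.center_lat, self.center_lon)
        return shapely.Polygon(zip(lon, lat))


def assign_hex_cells(
    hauls: pd.DataFrame, resolution: int, grid: HexGrid | None = None
) -> tuple[pd.Series, HexGrid]:
    """Assign every haul to a hexagonal cell; returns (ids, grid used).

    Without an explicit grid the tessellation is centred on the midpoint of
    the haul coordinate extent, so assignment is deterministic given the
    extent.
    """
    if grid is None:
        grid = HexGrid.for_extent(hauls["latitude"], hauls["longitude"], resolution)
    ids = grid.assign(hauls["latitude"].to_numpy(), hauls["longitude"].to_numpy())
    return pd.Series(ids, index=hauls.index, name=f"hex_r{resolution}"), grid


# -- BioTIME rectangular grid -------------------------------------------------

class BioTimeGrid:
    """5×5 grid over the latitude/longitude extent of one survey unit.

    Bins are half-open [edge, next_edge) with the final edge closed, so the
    maximum coordinate falls in the last row/column.  A degenerate extent
    (all hauls at one latitude or longitude) collapses to a single bin on
    that axis.
    """

    N = 5

    def __init__(self, lat_min, lat_max, lon_min, lon_max):
        self.lat_min, self.lat_max = float(lat_min), float(lat_max)
        self.lon_min, self.lon_max = float(lon_min), float(lon_max)

    @classmethod
    def for_extent(cls, latitudes, longitudes) -> "BioTimeGrid":
        lat = np.asarray(latitudes, dtype=float)
        lon = np.asarray(longitudes, dtype=float)
        return cls(lat.min(), lat.max(), lon.min(), lon.max())

    def _bin(self, x, lo, hi) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if hi <= lo:
            return np.zeros(x.shape, dtype=int)
        idx = np.floor((x - lo) / ((hi - lo) / self.N)).astype(int)
        return np.clip(idx, 0, self.N - 1)

    def assign(self, lat, lon) -> np.ndarray:
        rows = self._bin(lat, self.lat_min, self.lat_max)
        cols = self._bin(lon, self.lon_min, self.lon_max)
        return np.char.add(np.char.add(rows.astype(str), "-"), cols.astype(str))


def assign_biotime_cells(hauls: pd.DataFrame) -> pd.Series:
    """Assign hauls to the survey-specific 5×5 rectangular grid."""
    if len(hauls) == 0:
        raise DomainError("no hauls to grid")
    grid = BioTimeGrid.for_extent(hauls["latitude"], hauls["longitude"])
    ids = grid.assign(hauls["latitude"].to_numpy(), hauls["longitude"].to_numpy())
    return pd.Series(ids, index=hauls.index, name="biotime_cell")
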