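"""Regular lon/lat grids, gridded velocity fields, and land masks.

A velocity field stores the zonal and meridional current components
(u1 = dlon/dt, u2 = dlat/dt, both in degrees per day) at the nodes of a
regular grid.  Off-node values are obtained by bicubic spline
interpolation of each component, which is exact at the nodes; the splines
are built lazily and cached on the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .probe_data import GeoPoint, RegionBounds


@dataclass(frozen=True)
class Grid:
    """Regular lon/lat grid with node spacing ``spacing_deg`` (default 0.1)."""

    bounds: RegionBounds
    spacing_deg: float = 0.1

    @property
    def lons(self) -> np.ndarray:
        n = int(round((self.bounds.lon_max - self.bounds.lon_min) / self.spacing_deg))
        return self.bounds.lon_min + self.spacing_deg * np.arange(n + 1)

    @property
    def lats(self) -> np.ndarray:
        n = int(round((self.bounds.lat_max - self.bounds.lat_min) / self.spacing_deg))
        return self.bounds.lat_min + self.spacing_deg * np.arange(n + 1)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_lat, n_lon) node counts."""
        return (len(self.lats), len(self.lons))

    @property
    def n_cells(self) -> tuple[int, int]:
        """(n_lon_cells, n_lat_cells) grid-square counts."""
        return (len(self.lons) - 1, len(self.lats) - 1)

    def contains(self, lon, lat):
        return self.bounds.contains(lon, lat)

    def meshgrid(self):
        """Node coordinate arrays of shape (n_lat, n_lon)."""
        return np.meshgrid(self.lons, self.lats)


class VelocityField:
    """Gridded 2-D current field; components u1, u2 of shape (n_lat, n_lon)."""

    def __init__(self, grid: Grid, u1: np.ndarray, u2: np.ndarray):
        u1 = np.asarray(u1, dtype=float)
        u2 = np.asarray(u2, dtype=float)
        if u1.shape != grid.shape or u2.shape != grid.shape:
            raise ValueError(
                f"component shape {u1.shape} does not match grid {grid.shape}"
            )
        self.grid = grid
        self.u1 = u1
        self.u2 = u2
        self._splines = None

    def copy(self) -> "VelocityField":
        return VelocityField(self.grid, self.u1.copy(), self.u2.copy())

    def _build_splines(self):
        lats, lons = self.grid.lats, self.grid.lons
        # bicubic when the grid allows it, else highest odd degree that fits
        kx = min(3, len(lats) - 1)
        ky = min(3, len(lons) - 1)
        self._splines = (
            RectBivariateSpline(lats, lons, self.u1, kx=kx, ky=ky, s=0),
            RectBivariateSpline(lats, lons, self.u2, kx=kx, ky=ky, s=0),
        )

    def velocity(self, lon, lat, clip: bool = True):
        """Interpolated (u1, u2) at arbitrary points, deg/day.

        With ``clip`` (default) query points are clamped to the grid bounds,
        so the field is defined (constant-extended) just outside the domain;
        domain-exit handling is the integrator's responsibility.
        """
        if self._splines is None:
            self._build_splines()
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if clip:
            b = self.grid.bounds
            lon = np.clip(lon, b.lon_min, b.lon_max)
            lat = np.clip(lat, b.lat_min, b.lat_max)
        s1, s2 = self._splines
        return s1.ev(lat, lon), s2.ev(lat, lon)

    def speed(self) -> np.ndarray:
        return np.hypot(self.u1, self.u2)


@dataclass(frozen=True)
class LandMask:
    """Per-node boolean mask (True = land), same shape as its grid."""

    grid: Grid
    mask: np.ndarray

    def __post_init__(self):
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @classmethod
    def all_sea(cls, grid: Grid) -> "LandMask":
        return cls(grid, np.zeros(grid.shape, dtype=bool))


@dataclass
class FieldEnsemble:
    """A set of velocity-field realizations built from thinned data subsets."""

    fields: list[VelocityField]
    partition_label: str = ""
    master_seed: int | None = None

    def __post_init__(self):
        if self.fields:
            g0 = self.fields[0].grid
            if any(f.grid is not g0 and f.grid != g0 for f in self.fields):
                raise ValueError("all ensemble members must share one grid")

    def __len__(self):
        return len(self.fields)

    def __getitem__(self, i) -> VelocityField:
        return self.fields[i]

    @property
    def grid(self) -> Grid:
        return self.fields[0].grid

    def mean_field(self) -> VelocityField:
        u1 = np.mean([f.u1 for f in self.fields], axis=0)
        u2 = np.mean([f.u2 for f in self.fields], axis=0)
        return VelocityField(self.grid, u1, u2)


def rasterize_coastline(polygons, grid: Grid) -> LandMask:
    """Point-in-polygon rasterization of coastline polygons at grid nodes."""
    import shapely

    LON, LAT = grid.meshgrid()
    mask = np.zeros(grid.shape, dtype=bool)
    for poly in polygons:
        mask |= shapely.contains_xy(poly, LON.ravel(), LAT.ravel()).reshape(grid.shape)
    return LandMask(grid, mask)
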