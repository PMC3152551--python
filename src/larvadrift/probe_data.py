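"""Drifting-probe cycle records and their conversion to velocity observations.

Autonomous profiling floats (Argo probes) repeatedly dive to a parking
pressure, drift there for roughly ten days, resurface and transmit their
position.  The pair of surface fixes bracketing one dive-drift-resurface
cycle yields a single subsurface displacement, and hence one raw velocity
observation at the cycle's mid-point.  This module reads such cycle tables,
filters them by depth partition and study region, converts them to raw
velocity observations, and produces the randomly thinned observation
subsets used to build an ensemble of velocity fields.

All velocities are in degrees per day (longitude rate, latitude rate);
metric conversion happens only in :mod:`larvadrift.dispersal_summaries`.
Longitudes are kept in a continuous 0-360 frame so the south-west Pacific
study region does not straddle a discontinuity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Continuous 0-360 zonal band containing all station and probe data
#: (155-172 degrees E archipelagos; the band runs from 143 E across the
#: dateline to 176 W), and the 1.5-25 S latitude range of the study region.
STUDY_REGION_LON = (143.0, 184.0)
STUDY_REGION_LAT = (-25.0, -1.5)

CYCLE_COLUMNS = [
    "id",
    "lon_dive",
    "lat_dive",
    "lon_surface",
    "lat_surface",
    "duration_days",
    "depth_m",
]


def wrap_lon(lon):
    """Normalize longitudes into the continuous [0, 360) frame."""
    return np.asarray(lon, dtype=float) % 360.0


class GeoPoint(NamedTuple):
    """A geographic position: longitude (deg E, 0-360 frame), latitude (deg N)."""

    lon: float
    lat: float


@dataclass(frozen=True)
class ProbeCycle:
    """One dive-drift-resurface record of a drifting probe."""

    id: str
    x_dive: GeoPoint
    y_surface: GeoPoint
    duration_days: float
    drift_depth_m: float
    date: str | None = None

    def __post_init__(self):
        if not self.duration_days > 0:
            raise ValueError(f"cycle {self.id}: duration_days must be > 0")
        if not self.drift_depth_m > 0:
            raise ValueError(f"cycle {self.id}: drift_depth_m must be > 0")


@dataclass(frozen=True)
class RawVelocityObs:
    """A raw velocity observation: 2-vector v (deg/day) at mid-point X."""

    v: np.ndarray
    X: GeoPoint
    cycle_id: str


@dataclass(frozen=True)
class RegionBounds:
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self):
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("region bounds must satisfy min < max on both axes")

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )

    @classmethod
    def study_region(cls) -> "RegionBounds":
        return cls(*STUDY_REGION_LON, *STUDY_REGION_LAT)


@dataclass(frozen=True)
class DepthPartition:
    """Inclusive drift-depth band [depth_min_m, depth_max_m] in metres."""

    depth_min_m: float
    depth_max_m: float

    def __post_init__(self):
        if not (0 < self.depth_min_m < self.depth_max_m):
            raise ValueError("need 0 < depth_min_m < depth_max_m")

    def contains(self, depth_m) -> np.ndarray:
        depth_m = np.asarray(depth_m, dtype=float)
        return (depth_m >= self.depth_min_m) & (depth_m <= self.depth_max_m)


# -- ingestion ---------------------------------------------------------------


def read_cycles(path, format: str = "csv") -> list[ProbeCycle]:
    """Read probe cycles from a CSV or trajectory-style netCDF file.

    The CSV schema is ``id, lon_dive, lat_dive, lon_surface, lat_surface,
    duration_days, depth_m[, date]`` (date ISO-8601, optional).  Rows with
    missing coordinates or nonpositive duration/depth are dropped and
    counted in the log.
    """
    if format == "csv":
        try:
            df = pd.read_csv(path)
        except FileNotFoundError:
            raise FileNotFoundError(f"cycle file not found: {path}") from None
    elif format == "netcdf":
        import xarray as xr

        try:
            ds = xr.open_dataset(path, engine="scipy")
        except FileNotFoundError:
            raise FileNotFoundError(f"cycle file not found: {path}") from None
        df = ds.to_dataframe().reset_index()
    else:
        raise ValueError(f"unknown format: {format!r}")

    missing = [c for c in CYCLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cycle file {path} lacks required column(s): {missing}")
    return cycles_from_frame(df)


def cycles_from_frame(df: pd.DataFrame) -> list[ProbeCycle]:
    """Build ProbeCycle records from a schema-conforming DataFrame."""
    n_dropped = 0
    cycles: list[ProbeCycle] = []
    has_date = "date" in df.columns
    for row in df.itertuples(index=False):
        coords = (row.lon_dive, row.lat_dive, row.lon_surface, row.lat_surface)
        if any(pd.isna(c) for c in coords) or pd.isna(row.duration_days):
            n_dropped += 1
            continue
        if not (row.duration_days > 0 and row.depth_m > 0):
            n_dropped += 1
            continue
        cycles.append(
            ProbeCycle(
                id=str(row.id),
                x_dive=GeoPoint(float(wrap_lon(row.lon_dive)), float(row.lat_dive)),
                y_surface=GeoPoint(
                    float(wrap_lon(row.lon_surface)), float(row.lat_surface)
                ),
                duration_days=float(row.duration_days),
                drift_depth_m=float(row.depth_m),
                date=str(row.date) if has_date and not pd.isna(row.date) else None,
            )
        )
    if n_dropped:
        logger.info("dropped %d malformed cycle record(s)", n_dropped)
    cycles_from_frame.last_drop_count = n_dropped
    return cycles


def cycles_to_frame(cycles: Sequence[ProbeCycle]) -> pd.DataFrame:
    """Inverse of :func:`cycles_from_frame` (documented CSV schema)."""
    return pd.DataFrame(
        {
            "id": [c.id for c in cycles],
            "lon_dive": [c.x_dive.lon for c in cycles],
            "lat_dive": [c.x_dive.lat for c in cycles],
            "lon_surface": [c.y_surface.lon for c in cycles],
            "lat_surface": [c.y_surface.lat for c in cycles],
            "duration_days": [c.duration_days for c in cycles],
            "depth_m": [c.drift_depth_m for c in cycles],
            "date": [c.date for c in cycles],
        }
    )


# -- filtering and velocities ------------------------------------------------


@dataclass
class FilterResult:
    cycles: list[ProbeCycle]
    n_retained: int
    n_excluded: int

    def __iter__(self):
        return iter(self.cycles)

    def __len__(self):
        return len(self.cycles)


def filter_cycles(
    cycles: Sequence[ProbeCycle],
    region: RegionBounds,
    partition: DepthPartition,
) -> FilterResult:
    """Retain cycles in the depth partition whose mid-point lies in region."""
    kept = []
    for c in cycles:
        mid = cycle_midpoint(c)
        if partition.contains(c.drift_depth_m) and bool(
            region.contains(mid.lon, mid.lat)
        ):
            kept.append(c)
    return FilterResult(kept, len(kept), len(cycles) - len(kept))


def cycle_midpoint(cycle: ProbeCycle) -> GeoPoint:
    return GeoPoint(
        0.5 * (cycle.x_dive.lon + cycle.y_surface.lon),
        0.5 * (cycle.x_dive.lat + cycle.y_surface.lat),
    )


def raw_velocity(cycle: ProbeCycle) -> RawVelocityObs:
    """Displacement-forward raw velocity v = (y_surface - x_dive)/t, deg/day.

    The observation is anchored at the cycle mid-point
    X = (x_dive + y_surface)/2.
    """
    if not cycle.duration_days > 0:
        raise ValueError(f"cycle {cycle.id}: nonpositive duration")
    v = np.array(
        [
            (cycle.y_surface.lon - cycle.x_dive.lon) / cycle.duration_days,
            (cycle.y_surface.lat - cycle.x_dive.lat) / cycle.duration_days,
        ]
    )
    return RawVelocityObs(v=v, X=cycle_midpoint(cycle), cycle_id=cycle.id)


def raw_velocities(cycles: Sequence[ProbeCycle]) -> list[RawVelocityObs]:
    return [raw_velocity(c) for c in cycles]


# -- thinning ----------------------------------------------------------------


def thin_observations(
    obs: Sequence[RawVelocityObs],
    grid,
    rng: np.random.Generator,
    every: int = 4,
) -> list[RawVelocityObs]:
    """Randomly thin observations onto a sparse lattice of grid squares.

    Every ``every``-th grid square along each axis is selected (1/16 of the
    squares for the default spacing of 4), with the lattice phase drawn
    uniformly from the ``every**2`` possibilities, and from each selected
    square one observation whose mid-point lies inside it is picked at
    random.  Squares without observations contribute nothing.
    """
    phase_x = int(rng.integers(0, every))
    phase_y = int(rng.integers(0, every))
    h = grid.spacing_deg
    ncx, ncy = grid.n_cells

    # bucket observations by cell index
    buckets: dict[tuple[int, int], list[int]] = {}
    for k, o in enumerate(obs):
        ix = int(np.floor((o.X.lon - grid.bounds.lon_min) / h))
        iy = int(np.floor((o.X.lat - grid.bounds.lat_min) / h))
        if 0 <= ix < ncx and 0 <= iy < ncy:
            if ix % every == phase_x and iy % every == phase_y:
                buckets.setdefault((ix, iy), []).append(k)

    picked = []
    for key in sorted(buckets):
        idxs = buckets[key]
        picked.append(obs[idxs[int(rng.integers(0, len(idxs)))]])
    return picked
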