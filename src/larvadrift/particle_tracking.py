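"""Passive Lagrangian particle tracking through gridded velocity fields.

Larvae are advected as passive particles: dr/dt = u(r), with r = (lon, lat)
in degrees and u in degrees per day, integrated with an explicit
Runge-Kutta (2,3) scheme.  A dispersal cohort releases particles from
benthic source stations (station chosen in proportion to specimen
abundance, release point Gaussian-scattered about the station), and each
particle switches daily among a small personal set of ensemble velocity
fields so that the ensemble's variability enters the trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .grids import FieldEnsemble, VelocityField
from .probe_data import GeoPoint

logger = logging.getLogger(__name__)

#: Default integrator tolerances (relative, absolute-degrees), chosen so the
#: 500-day solid-rotation orbit-radius oracle passes with a wide margin.
DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-8


@dataclass(frozen=True)
class SourceStation:
    """A benthic source population: location, depth range, abundance, group."""

    station_id: str
    location: GeoPoint
    depth_min_m: float
    depth_max_m: float
    abundance: int
    group: str

    def __post_init__(self):
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")
        if self.depth_min_m > self.depth_max_m:
            raise ValueError("depth_min_m must be <= depth_max_m")


@dataclass(frozen=True)
class CohortConfig:
    """Release and integration settings for one simulated larval cohort."""

    n_particles: int = 10000
    duration_days: int = 500
    fields_per_particle: int = 5
    start_sd_deg: float = 0.1
    report_times: tuple[int, ...] = (50, 100, 250, 500)
    seed: int = 0
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL

    def __post_init__(self):
        if min(self.n_particles, self.duration_days, self.fields_per_particle) < 1:
            raise ValueError("counts must be positive")
        if any(t > self.duration_days for t in self.report_times):
            raise ValueError("report_times must not exceed duration_days")


@dataclass
class Trajectory:
    """Daily particle positions with provenance.

    ``lons``/``lats`` hold positions at whole days 0..d where d is the last
    recorded day (== duration for completed particles, the exit day for
    particles that left the domain).
    """

    particle_id: int
    station_id: str
    lons: np.ndarray
    lats: np.ndarray
    status: str = "completed"  # or "left_domain"
    exit_day: int | None = None
    field_schedule: np.ndarray | None = None  # ensemble member index per day

    @property
    def n_days(self) -> int:
        return len(self.lons) - 1

    def position(self, day: int) -> GeoPoint:
        return GeoPoint(float(self.lons[day]), float(self.lats[day]))


# -- field evaluation and integration ---------------------------------------


def field_velocity(field: VelocityField, point: GeoPoint):
    """Bicubic-interpolated velocity (deg/day) at a point inside the grid."""
    if not bool(field.grid.contains(point.lon, point.lat)):
        raise ValueError(f"point {point} outside grid bounds")
    u1, u2 = field.velocity(point.lon, point.lat)
    return np.array([float(u1), float(u2)])


def _boundary_event(field: VelocityField):
    b = field.grid.bounds

    def hit_boundary(t, r):
        return min(
            r[0] - b.lon_min, b.lon_max - r[0], r[1] - b.lat_min, b.lat_max - r[1]
        )

    hit_boundary.terminal = True
    hit_boundary.direction = -1
    return hit_boundary


def advect(
    field: VelocityField,
    lon0: float,
    lat0: float,
    t_span: tuple[float, float],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    t_eval=None,
):
    """Advect a single particle through one (static) field with RK(2,3).

    Returns ``(sol, exited)`` where ``sol`` is the solver result and
    ``exited`` is True when the trajectory reached the grid boundary (the
    integration then stops at the exit point).
    """

    def rhs(t, r):
        u1, u2 = field.velocity(r[0], r[1])
        return [float(u1), float(u2)]

    sol = solve_ivp(
        rhs,
        t_span,
        [lon0, lat0],
        method="RK23",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        events=[_boundary_event(field)],
        dense_output=False,
    )
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"integration failed: {sol.message}")
    exited = sol.status == 1 and len(sol.t_events[0]) > 0
    return sol, exited


def integrate_path(
    field_schedule: Callable[[int], VelocityField],
    r0: GeoPoint,
    duration_days: int,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    particle_id: int = 0,
    station_id: str = "",
) -> Trajectory:
    """Integrate one particle, day by day, under a daily field schedule.

    Advection is autonomous within each day under ``field_schedule(day)``;
    the schedule's piecewise-constant daily switching is the only time
    dependence.  Positions are logged at whole days.  A particle reaching
    the grid boundary terminates with status ``left_domain`` and keeps its
    partial track (the exit point is the final logged position).
    """
    lons = [r0.lon]
    lats = [r0.lat]
    status, exit_day = "completed", None
    for day in range(duration_days):
        fld = field_schedule(day)
        sol, exited = advect(
            fld, lons[-1], lats[-1], (0.0, 1.0), rtol=rtol, atol=atol
        )
        if not np.all(np.isfinite(sol.y[:, -1])):
            status, exit_day = "invalid", day + 1
            break
        lons.append(float(sol.y[0, -1]))
        lats.append(float(sol.y[1, -1]))
        if exited:
            status, exit_day = "left_domain", day + 1
            break
    return Trajectory(
        particle_id=particle_id,
        station_id=station_id,
        lons=np.array(lons),
        lats=np.array(lats),
        status=status,
        exit_day=exit_day,
    )


# -- cohort release ----------------------------------------------------------


def sample_start(
    stations: Sequence[SourceStation],
    sd_deg: float,
    rng: np.random.Generator,
) -> tuple[GeoPoint, str]:
    """Abundance-weighted station choice plus isotropic Gaussian offset."""
    if not stations:
        raise ValueError("empty station list")
    abund = np.array([s.abundance for s in stations], dtype=float)
    idx = int(rng.choice(len(stations), p=abund / abund.sum()))
    st = stations[idx]
    dlon, dlat = rng.normal(0.0, sd_deg, size=2) if sd_deg > 0 else (0.0, 0.0)
    return GeoPoint(st.location.lon + dlon, st.location.lat + dlat), st.station_id


def simulate_cohort(
    ensemble: FieldEnsemble,
    stations: Sequence[SourceStation],
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> list[Trajectory]:
    """Simulate a cohort of passively dispersing larvae.

    For each particle: draw ``fields_per_particle`` ensemble members
    (without replacement when the ensemble is large enough, otherwise with
    replacement, logged), draw an abundance-weighted Gaussian release
    point, and advect with a uniform daily choice among the personal
    member set.  Fully reproducible from ``config.seed``.
    """
    if len(ensemble) == 0:
        raise ValueError("empty field ensemble")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    k = config.fields_per_particle
    replace = len(ensemble) < k
    if replace:
        logger.warning(
            "ensemble size %d < fields_per_particle %d: drawing with replacement",
            len(ensemble),
            k,
        )

    # all random draws happen up front, in particle order, so trajectories
    # are reproducible regardless of integration batching
    starts, station_ids, schedules = [], [], []
    for _ in range(config.n_particles):
        members = rng.choice(len(ensemble), size=k, replace=replace)
        start, sid = sample_start(stations, config.start_sd_deg, rng)
        daily = members[rng.integers(0, k, size=config.duration_days)]
        starts.append(start)
        station_ids.append(sid)
        schedules.append(daily)

    return _advect_cohort(ensemble, starts, station_ids, schedules, config)


def _advect_cohort(ensemble, starts, station_ids, schedules, config):
    """Day-by-day advection of many particles, batched by field member."""
    n = len(starts)
    dur = config.duration_days
    b = ensemble.grid.bounds
    lons = np.full((n, dur + 1), np.nan)
    lats = np.full((n, dur + 1), np.nan)
    lons[:, 0] = [s.lon for s in starts]
    lats[:, 0] = [s.lat for s in starts]
    active = np.ones(n, dtype=bool)
    exit_day = np.full(n, -1, dtype=int)

    # particles released outside the domain leave immediately
    out0 = ~ensemble.grid.contains(lons[:, 0], lats[:, 0])
    if np.any(out0):
        lons[out0, 0] = np.clip(lons[out0, 0], b.lon_min, b.lon_max)
        lats[out0, 0] = np.clip(lats[out0, 0], b.lat_min, b.lat_max)
        active[out0] = False
        exit_day[out0] = 0

    sched = np.asarray(schedules)
    for day in range(dur):
        if not np.any(active):
            break
        todays = sched[:, day]
        for m in np.unique(todays[active]):
            idx = np.flatnonzero(active & (todays == m))
            fld = ensemble[int(m)]

            def rhs(t, y, fld=fld, npts=len(idx)):
                lon = np.clip(y[:npts], b.lon_min, b.lon_max)
                lat = np.clip(y[npts:], b.lat_min, b.lat_max)
                u1, u2 = fld.velocity(lon, lat, clip=False)
                return np.concatenate([np.atleast_1d(u1), np.atleast_1d(u2)])

            y0 = np.concatenate([lons[idx, day], lats[idx, day]])
            sol = solve_ivp(
                rhs, (0.0, 1.0), y0, method="RK23",
                rtol=config.rtol, atol=config.atol,
            )
            yend = sol.y[:, -1]
            npts = len(idx)
            new_lon, new_lat = yend[:npts], yend[npts:]
            out = ~ensemble.grid.contains(new_lon, new_lat)
            new_lon = np.clip(new_lon, b.lon_min, b.lon_max)
            new_lat = np.clip(new_lat, b.lat_min, b.lat_max)
            lons[idx, day + 1] = new_lon
            lats[idx, day + 1] = new_lat
            if np.any(out):
                left = idx[out]
                active[left] = False
                exit_day[left] = day + 1

    trajectories = []
    for p in range(n):
        last = exit_day[p] if exit_day[p] >= 0 else dur
        trajectories.append(
            Trajectory(
                particle_id=p,
                station_id=station_ids[p],
                lons=lons[p, : last + 1].copy(),
                lats=lats[p, : last + 1].copy(),
                status="left_domain" if exit_day[p] >= 0 else "completed",
                exit_day=int(exit_day[p]) if exit_day[p] >= 0 else None,
                field_schedule=sched[p].copy(),
            )
        )
    return trajectories


def stations_from_frame(df) -> list[SourceStation]:
    """Build stations from the documented CSV schema (station_id, lon, lat,
    depth_min_m, depth_max_m, abundance, group)."""
    from .probe_data import wrap_lon

    return [
        SourceStation(
            station_id=str(r.station_id),
            location=GeoPoint(float(wrap_lon(r.lon)), float(r.lat)),
            depth_min_m=float(r.depth_min_m),
            depth_max_m=float(r.depth_max_m),
            abundance=int(r.abundance),
            group=str(r.group),
        )
        for r in df.itertuples(index=False)
    ]


def trajectories_to_frame(trajectories: Sequence[Trajectory]):
    """Long-format (particle, day, lon, lat) DataFrame for CSV output."""
    import pandas as pd

    rows = []
    for tr in trajectories:
        days = np.arange(len(tr.lons))
        rows.append(
            pd.DataFrame(
                {
                    "particle_id": tr.particle_id,
                    "station_id": tr.station_id,
                    "day": days,
                    "lon": tr.lons,
                    "lat": tr.lats,
                    "status": tr.status,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
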