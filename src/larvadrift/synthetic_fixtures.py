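"""Synthetic inputs with known ground truth for every pipeline stage.

Everything the pipeline consumes can be generated here: analytic velocity
fields (with exact evaluators usable as oracles), probe cycles drifted
through those fields, clustered station tables emulating the deep-sea
chiton survey, a toy coastline/bathymetry pair, and PLD datasets drawn
from the exponential-quadratic generative model.  The defaults encode the
study's stated conditions (probe-census strata sizes, station counts per
archipelago, specimen totals, survey depth span, PLD model parameters);
the fixtures are oracles, not simulations of the Coral Sea.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .grids import Grid, VelocityField
from .particle_tracking import SourceStation, advect
from .probe_data import GeoPoint, ProbeCycle, RegionBounds

#: Stated composition of the nine-year probe census by drift-depth stratum:
#: (depth_min_m, depth_max_m, n_cycles).  225 cycles shallower than 800 m,
#: 4915 at 800-1400 m, 4723 at 1400-2500 m, 13 below 2500 m.
PROBE_CENSUS_STRATA = (
    (50.0, 800.0, 225),
    (800.0, 1400.0, 4915),
    (1400.0, 2500.0, 4723),
    (2500.0, 3500.0, 13),
)

#: Archipelago cluster geometry emulating the survey station table:
#: (group, centre lon E, centre lat, n stations, cluster scale deg).
ARCHIPELAGO_CLUSTERS = (
    ("New Caledonia", 165.9, -21.7, 17, 0.65),
    ("Vanuatu", 167.1, -15.9, 50, 0.65),
    ("Solomon Islands", 160.2, -8.9, 56, 0.95),
)

#: Total specimen abundance across all stations.
TOTAL_SPECIMENS = 1070

#: Station depth span (m) of the survey (shallowest/deepest sampling depth).
SURVEY_DEPTH_SPAN_M = (197.0, 1620.0)

#: Default peak speed of the study-like gyre field, deg/day (about 8 cm/s
#: at the peak, a few cm/s over most of the domain - typical observed
#: deep-current magnitudes at intermediate depths).
GYRE_PEAK_SPEED = 0.065


@dataclass(frozen=True)
class AnalyticFieldSpec:
    """An analytic velocity field evaluable anywhere (the exact oracle).

    kinds: ``uniform`` (params u1, u2), ``solid_rotation`` (centre,
    omega_per_day), ``linear`` (a1, b1, a2, b2, origin), ``double_gyre``
    (region, amplitude = peak speed, cells nx/ny).
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __call__(self, lon, lat):
        return self.evaluate(lon, lat)

    def evaluate(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        p = self.params
        if self.kind == "uniform":
            shape = np.broadcast(lon, lat).shape
            return np.full(shape, p["u1"]), np.full(shape, p["u2"])
        if self.kind == "solid_rotation":
            clon, clat = p["center"]
            w = p["omega_per_day"]
            return -w * (lat - clat), w * (lon - clon)
        if self.kind == "linear":
            lon0, lat0 = p.get("origin", (0.0, 0.0))
            return (
                p["a1"] + p["b1"] * (lon - lon0),
                p["a2"] + p["b2"] * (lat - lat0),
            )
        if self.kind == "double_gyre":
            b: RegionBounds = p["region"]
            nx, ny = p.get("cells", (2, 1))
            A = p.get("amplitude", GYRE_PEAK_SPEED)
            kx = nx * math.pi / (b.lon_max - b.lon_min)
            ky = ny * math.pi / (b.lat_max - b.lat_min)
            X = kx * (lon - b.lon_min)
            Y = ky * (lat - b.lat_min)
            # streamfunction psi = (A/kmax) sin X sin Y; peak speed = A
            kmax = max(kx, ky)
            u1 = -(A * ky / kmax) * np.sin(X) * np.cos(Y)
            u2 = (A * kx / kmax) * np.cos(X) * np.sin(Y)
            return u1, u2
        raise ValueError(f"unknown analytic field kind: {self.kind!r}")


def closed_form_endpoint(spec: AnalyticFieldSpec, lon0, lat0, t):
    """Exact trajectory endpoint after time t, or None if no closed form."""
    p = spec.params
    if spec.kind == "uniform":
        return lon0 + p["u1"] * t, lat0 + p["u2"] * t
    if spec.kind == "solid_rotation":
        clon, clat = p["center"]
        th = p["omega_per_day"] * t
        dx, dy = lon0 - clon, lat0 - clat
        return (
            clon + math.cos(th) * dx - math.sin(th) * dy,
            clat + math.sin(th) * dx + math.cos(th) * dy,
        )
    if spec.kind == "linear":
        lon0_, lat0_ = p.get("origin", (0.0, 0.0))

        def solve(x, a, b, x0):
            if b == 0:
                return x + a * t
            w = x - x0 + a / b
            return x0 - a / b + w * math.exp(b * t)

        return (
            solve(lon0, p["a1"], p["b1"], lon0_),
            solve(lat0, p["a2"], p["b2"], lat0_),
        )
    return None


def make_analytic_field(spec: AnalyticFieldSpec, grid: Grid):
    """Exact node evaluations on the grid, plus the continuous evaluator."""
    LON, LAT = grid.meshgrid()
    u1, u2 = spec.evaluate(LON, LAT)
    return VelocityField(grid, u1, u2), spec


def study_like_gyre(region: RegionBounds, amplitude: float = GYRE_PEAK_SPEED):
    """A basin-filling double-gyre field at realistic deep-current speeds."""
    return AnalyticFieldSpec(
        "double_gyre", {"region": region, "amplitude": amplitude, "cells": (2, 1)}
    )


# -- probe cycles ------------------------------------------------------------


def make_synthetic_cycles(
    spec: AnalyticFieldSpec,
    n: int,
    region: RegionBounds,
    rng: np.random.Generator,
    mean_duration_days: float = 10.0,
    duration_jitter: float = 0.2,
    noise_sd_deg: float = 0.0,
    depth_m: float = 1000.0,
    margin_deg: float = 0.0,
    grid_for_integration: Grid | None = None,
) -> tuple[list[ProbeCycle], pd.DataFrame]:
    """Cycles drifted through an analytic field, plus their ground truth.

    Dive points are uniform in the (margin-shrunk) region, durations are
    jittered uniformly about the mean, and the resurface point is the
    exact integration endpoint plus optional Gaussian position noise.
    The returned frame retains noise-free endpoints per cycle.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lon0 = rng.uniform(region.lon_min + margin_deg, region.lon_max - margin_deg, n)
    lat0 = rng.uniform(region.lat_min + margin_deg, region.lat_max - margin_deg, n)
    t = mean_duration_days * rng.uniform(1 - duration_jitter, 1 + duration_jitter, n)

    integ_field = None
    if closed_form_endpoint(spec, 0.0, 0.0, 1.0) is None:
        g = grid_for_integration or Grid(region, spacing_deg=max(
            (region.lon_max - region.lon_min) / 60.0, 1e-3
        ))
        integ_field, _ = make_analytic_field(spec, g)

    cycles, rows = [], []
    for k in range(n):
        end = closed_form_endpoint(spec, lon0[k], lat0[k], t[k])
        if end is None:
            sol, _ = advect(
                integ_field, lon0[k], lat0[k], (0.0, t[k]), rtol=1e-9, atol=1e-11
            )
            end = (float(sol.y[0, -1]), float(sol.y[1, -1]))
        noise = rng.normal(0.0, noise_sd_deg, 2) if noise_sd_deg > 0 else (0.0, 0.0)
        cycles.append(
            ProbeCycle(
                id=f"syn{k:05d}",
                x_dive=GeoPoint(lon0[k], lat0[k]),
                y_surface=GeoPoint(end[0] + noise[0], end[1] + noise[1]),
                duration_days=float(t[k]),
                drift_depth_m=depth_m,
            )
        )
        rows.append(
            {"id": f"syn{k:05d}", "lon_true": end[0], "lat_true": end[1],
             "duration_days": t[k]}
        )
    return cycles, pd.DataFrame(rows)


def make_synthetic_probe_dataset(
    rng: np.random.Generator,
    region: RegionBounds | None = None,
    strata=PROBE_CENSUS_STRATA,
    spec: AnalyticFieldSpec | None = None,
) -> list[ProbeCycle]:
    """Synthetic stand-in for the full nine-year probe census.

    One cycle per record of the stated census composition: drift depths
    uniform within each stratum, cycles drifted through a uniform field
    at a typical deep-current speed.  This is a labelled synthetic
    surrogate for the unavailable archive file; only its composition is
    meaningful.
    """
    region = region or RegionBounds.study_region()
    spec = spec or AnalyticFieldSpec("uniform", {"u1": -0.03, "u2": 0.01})
    out: list[ProbeCycle] = []
    for dmin, dmax, count in strata:
        cycles, _ = make_synthetic_cycles(
            spec, count, region, rng, noise_sd_deg=0.005, margin_deg=1.0
        )
        depths = rng.uniform(dmin, dmax, count)
        for c, d in zip(cycles, depths):
            out.append(
                ProbeCycle(
                    id=f"{c.id}_d{int(dmin)}",
                    x_dive=c.x_dive,
                    y_surface=c.y_surface,
                    duration_days=c.duration_days,
                    drift_depth_m=float(d),
                )
            )
    return out


# -- stations ----------------------------------------------------------------


def make_synthetic_stations(
    n_groups: int,
    stations_per_group,
    cluster_scale_deg,
    rng: np.random.Generator,
    centers: Sequence[tuple[float, float]] | None = None,
    group_names: Sequence[str] | None = None,
    abundance_total: int | None = None,
    depth_span_m: tuple[float, float] = SURVEY_DEPTH_SPAN_M,
) -> list[SourceStation]:
    """Clustered station groups with integer abundances >= 1.

    Stations scatter isotropically (Gaussian, per-axis SD = cluster
    scale) about each group centre; abundances follow a heavy-tailed
    (lognormal) law, rescaled to the requested total with every station
    keeping at least one specimen.  Station depth maxima are drawn across
    the survey span with the extremes pinned to it.
    """
    if np.isscalar(stations_per_group):
        stations_per_group = [int(stations_per_group)] * n_groups
    if np.isscalar(cluster_scale_deg):
        cluster_scale_deg = [float(cluster_scale_deg)] * n_groups
    if centers is None:
        centers = [(150.0 + 8.0 * g, -20.0 + 4.0 * g) for g in range(n_groups)]
    if group_names is None:
        group_names = [f"group{g}" for g in range(n_groups)]

    n_total = int(sum(stations_per_group))
    weights = rng.lognormal(0.0, 1.2, n_total)
    if abundance_total is None:
        abund = np.maximum(1, np.round(weights * 10).astype(int))
    else:
        extra = abundance_total - n_total
        if extra < 0:
            raise ValueError("abundance_total smaller than station count")
        abund = 1 + rng.multinomial(extra, weights / weights.sum())

    dmax = rng.uniform(depth_span_m[0], depth_span_m[1], n_total)
    dmax[np.argmin(dmax)] = depth_span_m[0]
    dmax[np.argmax(dmax)] = depth_span_m[1]
    dmin = np.maximum(150.0, dmax - rng.uniform(30.0, 300.0, n_total))

    stations, k = [], 0
    for g in range(n_groups):
        clon, clat = centers[g]
        for _ in range(stations_per_group[g]):
            stations.append(
                SourceStation(
                    station_id=f"st{k:03d}",
                    location=GeoPoint(
                        clon + rng.normal(0.0, cluster_scale_deg[g]),
                        clat + rng.normal(0.0, cluster_scale_deg[g]),
                    ),
                    depth_min_m=float(dmin[k]),
                    depth_max_m=float(dmax[k]),
                    abundance=int(abund[k]),
                    group=group_names[g],
                )
            )
            k += 1
    return stations


def dataset_s3_like_stations(rng: np.random.Generator) -> list[SourceStation]:
    """Synthetic stand-in for the survey station table.

    Three archipelago clusters at the expeditions' approximate centres
    with the recorded numbers of locations (17 New Caledonia, 50 Vanuatu,
    56 Solomon Islands), 1070 specimens in total, and sampling depths
    spanning 197-1620 m.
    """
    names = [c[0] for c in ARCHIPELAGO_CLUSTERS]
    centers = [(c[1], c[2]) for c in ARCHIPELAGO_CLUSTERS]
    counts = [c[3] for c in ARCHIPELAGO_CLUSTERS]
    scales = [c[4] for c in ARCHIPELAGO_CLUSTERS]
    return make_synthetic_stations(
        n_groups=3,
        stations_per_group=counts,
        cluster_scale_deg=scales,
        rng=rng,
        centers=centers,
        group_names=names,
        abundance_total=TOTAL_SPECIMENS,
    )


# -- PLD records -------------------------------------------------------------


def make_synthetic_pld_data(
    rng: np.random.Generator,
    beta: tuple[float, float, float] = (2.95, -1.30, -0.26),
    tau2: float = 0.92,
    sigma2: float = 0.03,
    Tc: float = 15.0,
    n_species: int = 20,
    records_per_species: int = 5,
    T_range: tuple[float, float] = (5.0, 25.0),
    feeding_mode: str = "lecithotrophic",
) -> tuple[pd.DataFrame, dict]:
    """PLD records drawn exactly from the generative mixed model.

    Returns the record frame and the true species intercept offsets
    (for parameter-recovery tests).
    """
    if tau2 < 0 or sigma2 < 0:
        raise ValueError("variances must be >= 0")
    b0, b1, b2 = beta
    u0 = rng.normal(0.0, math.sqrt(tau2), n_species) if tau2 > 0 else np.zeros(n_species)
    rows = []
    for i in range(n_species):
        T = rng.uniform(T_range[0], T_range[1], records_per_species)
        z = np.log(T / Tc)
        eps = (
            rng.normal(0.0, math.sqrt(sigma2), records_per_species)
            if sigma2 > 0
            else np.zeros(records_per_species)
        )
        ln_pld = b0 + u0[i] + b1 * z + b2 * z**2 + eps
        for Tij, y in zip(T, ln_pld):
            rows.append(
                {
                    "species": f"species{i:02d}",
                    "feeding_mode": feeding_mode,
                    "T_celsius": float(Tij),
                    "pld_days": float(np.exp(y)),
                }
            )
    truth = {f"species{i:02d}": float(u0[i]) for i in range(n_species)}
    return pd.DataFrame(rows), truth


# -- coastline and bathymetry ------------------------------------------------


@dataclass(frozen=True)
class BathymetryRaster:
    """ETOPO-convention elevation raster (negative = below sea level)."""

    lons: np.ndarray
    lats: np.ndarray
    elevation: np.ndarray  # shape (n_lat, n_lon)


@dataclass
class SyntheticCoast:
    polygons: list
    raster: BathymetryRaster
    elevation_fn: Callable


def make_synthetic_coast_and_bathymetry(
    region: RegionBounds,
    islands: Sequence[tuple[float, float, float]] = (),
    spacing_deg: float = 0.1,
    shelf_slope_m_per_deg: float = 2000.0,
    floor_m: float = -4000.0,
) -> SyntheticCoast:
    """Conical islands on a flat abyssal plain, with matching coastline.

    Each island is (centre lon, centre lat, coast radius deg): elevation
    rises linearly toward the centre at ``shelf_slope_m_per_deg`` and
    crosses zero exactly at the coast radius, so the land polygons (discs
    of that radius) agree with elevation > 0 and any depth contour is an
    analytic annulus.
    """
    import shapely

    def elevation(lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        z = np.full(np.broadcast(lon, lat).shape, floor_m)
        for clon, clat, r0 in islands:
            d = np.hypot(lon - clon, lat - clat)
            z = np.maximum(z, shelf_slope_m_per_deg * (r0 - d))
        return z

    grid = Grid(region, spacing_deg=spacing_deg)
    LON, LAT = grid.meshgrid()
    raster = BathymetryRaster(grid.lons, grid.lats, elevation(LON, LAT))
    polygons = [
        shapely.Point(clon, clat).buffer(r0, quad_segs=90)
        for clon, clat, r0 in islands
    ]
    return SyntheticCoast(polygons=polygons, raster=raster, elevation_fn=elevation)
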