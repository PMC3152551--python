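"""Eulerian velocity-field reconstruction from probe displacement data.

The reconstruction follows a zeroth-order, Kalman-style optimal
interpolation: an initial gridded estimate is obtained by triangle-based
cubic interpolation of the raw cycle velocities; each probe cycle is then
simulated through the current field estimate, and the velocity residual
v(n) - v_b(n) between the observed and simulated cycle velocity is spread
onto the grid by three localized kernels anchored at the cycle's start,
simulated mid-point, and simulated end.  The nodewise update is the
weight-normalized residual average scaled by the gain
alpha = 1 / (1 + (sigma_o/sigma_b)^2), and the correction is iterated
(three passes by default), each pass restarting from the corrected field.

An ensemble of such fields is built from randomly thinned data subsets,
capturing the inter-annual variability that a single all-data field would
average away.  Finally, coastal vectors that point toward land are rotated
through the smallest angle that makes them point to sea (speeds are
preserved), so particle paths cannot cross large land areas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator, NearestNDInterpolator

from .grids import FieldEnsemble, Grid, LandMask, VelocityField
from .particle_tracking import DEFAULT_ATOL, DEFAULT_RTOL, advect
from .probe_data import (
    GeoPoint,
    ProbeCycle,
    RawVelocityObs,
    raw_velocity,
    thin_observations,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssimilationConfig:
    """Settings of the iterative optimal-interpolation correction.

    sigma_ratio is sigma_o/sigma_b, the error of the observed probe
    positions relative to the simulated trajectories; the probe fixes are
    taken an order of magnitude more precise than the simulation
    (default 0.1).  kernel_scale defaults to the grid spacing h.
    """

    sigma_ratio: float = 0.1
    iterations: int = 3
    kernel_scale: float | None = None  # None -> grid spacing
    kernel_cutoff: float = 3.0  # kernel support radius, in units of scale
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL

    def __post_init__(self):
        if self.sigma_ratio <= 0:
            raise ValueError("sigma_ratio must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def alpha(self) -> float:
        """Gain alpha, with alpha^-1 = 1 + (sigma_o/sigma_b)^2."""
        return 1.0 / (1.0 + self.sigma_ratio**2)


@dataclass(frozen=True)
class PredictedCycle:
    """Simulated counterpart of a probe cycle under a candidate field."""

    y_pred: GeoPoint
    v_model: np.ndarray
    X_model: GeoPoint
    exited: bool = False


# -- initial estimate --------------------------------------------------------


def initial_field(obs: Sequence[RawVelocityObs], grid: Grid) -> VelocityField:
    """Triangle-based cubic interpolation of raw velocities onto the grid.

    Each velocity component is interpolated independently
    (Clough-Tocher on a Delaunay triangulation); nodes outside the
    observations' convex hull take the nearest observation's value, since
    cubic extrapolation is unstable and exterior nodes are later
    constrained by the assimilation and the land correction.
    """
    if len(obs) < 3:
        raise ValueError(f"need >= 3 observations for interpolation, got {len(obs)}")
    pts = np.array([[o.X.lon, o.X.lat] for o in obs])
    vals = np.array([o.v for o in obs])
    LON, LAT = grid.meshgrid()
    comps = []
    for k in range(2):
        try:
            interp = CloughTocher2DInterpolator(pts, vals[:, k])
        except Exception as exc:  # collinear / degenerate triangulation
            raise ValueError(f"degenerate observation geometry: {exc}") from exc
        z = interp(LON, LAT)
        hole = ~np.isfinite(z)
        if np.any(hole):
            nearest = NearestNDInterpolator(pts, vals[:, k])
            z[hole] = nearest(LON[hole], LAT[hole])
        comps.append(z)
    return VelocityField(grid, comps[0], comps[1])


# -- cycle simulation --------------------------------------------------------


def simulate_cycle(
    field: VelocityField,
    cycle: ProbeCycle,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> PredictedCycle:
    """Predict a cycle's resurface point by advecting its dive point.

    Returns the predicted endpoint y_b, the model cycle velocity
    v_b = (y_b - x_dive)/t, and the model mid-point X_b = (y_b + x_dive)/2.
    A trajectory that reaches the grid boundary stops there (the exit
    point is the endpoint) and is flagged, but still contributes.
    """
    if not bool(field.grid.contains(cycle.x_dive.lon, cycle.x_dive.lat)):
        raise ValueError(f"cycle {cycle.id}: dive point outside grid bounds")
    sol, exited = advect(
        field,
        cycle.x_dive.lon,
        cycle.x_dive.lat,
        (0.0, cycle.duration_days),
        rtol=rtol,
        atol=atol,
    )
    y = GeoPoint(float(sol.y[0, -1]), float(sol.y[1, -1]))
    v_model = (
        np.array([y.lon - cycle.x_dive.lon, y.lat - cycle.x_dive.lat])
        / cycle.duration_days
    )
    X_model = GeoPoint(
        0.5 * (y.lon + cycle.x_dive.lon), 0.5 * (y.lat + cycle.x_dive.lat)
    )
    return PredictedCycle(y_pred=y, v_model=v_model, X_model=X_model, exited=exited)


# -- assimilation ------------------------------------------------------------


def _kernel(grid: Grid, anchor: GeoPoint, scale: float, cutoff: float) -> np.ndarray:
    """Isotropic Gaussian exp(-|x_ij - anchor|^2 / (2 scale^2)), truncated."""
    LON, LAT = grid.meshgrid()
    d2 = (LON - anchor.lon) ** 2 + (LAT - anchor.lat) ** 2
    w = np.exp(-d2 / (2.0 * scale**2))
    w[d2 > (cutoff * scale) ** 2] = 0.0
    return w


def assimilation_weights(
    grid: Grid,
    x_dive: GeoPoint,
    X_model: GeoPoint,
    y_pred: GeoPoint,
    kernel_scale: float | None = None,
    kernel_cutoff: float = 3.0,
):
    """Per-node weights (gamma1, gamma2, gamma3) localized at the cycle's
    start, simulated mid-point, and simulated end."""
    scale = grid.spacing_deg if kernel_scale is None else kernel_scale
    return (
        _kernel(grid, x_dive, scale, kernel_cutoff),
        _kernel(grid, X_model, scale, kernel_cutoff),
        _kernel(grid, y_pred, scale, kernel_cutoff),
    )


def assimilate(
    field0: VelocityField,
    obs: Sequence[RawVelocityObs],
    cycles: Sequence[ProbeCycle],
    config: AssimilationConfig = AssimilationConfig(),
) -> VelocityField:
    """Iteratively correct a field so simulated cycles match the data.

    Each pass simulates every cycle through the current field, forms the
    shared residual v(n) - v_b(n), and updates every node by alpha times
    the kernel-weighted residual average (the three anchor kernels enter
    additively; the per-node normalization is the summed weight over all
    cycles, so an isolated cycle corrects its anchors by almost the full
    residual while overlapping cycles average).
    """
    if len(obs) != len(cycles):
        raise ValueError("obs and cycles must be aligned")
    field = field0.copy()
    scale = config.kernel_scale or field.grid.spacing_deg
    for _ in range(config.iterations):
        num = np.zeros(field.grid.shape + (2,))
        den = np.zeros(field.grid.shape)
        for o, c in zip(obs, cycles):
            pred = simulate_cycle(field, c, rtol=config.rtol, atol=config.atol)
            dv = o.v - pred.v_model
            if not np.all(np.isfinite(dv)):
                logger.warning("cycle %s: non-finite residual, dropped", c.id)
                continue
            g1, g2, g3 = assimilation_weights(
                field.grid, c.x_dive, pred.X_model, pred.y_pred,
                kernel_scale=scale, kernel_cutoff=config.kernel_cutoff,
            )
            w = g1 + g2 + g3
            num += w[:, :, None] * dv
            den += w
        upd = np.where(
            den[:, :, None] > 1e-12, num / np.maximum(den, 1e-12)[:, :, None], 0.0
        )
        field = VelocityField(
            field.grid,
            field.u1 + config.alpha * upd[:, :, 0],
            field.u2 + config.alpha * upd[:, :, 1],
        )
    return field


# -- land correction ---------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def land_correct(field: VelocityField, mask: LandMask) -> VelocityField:
    """Rotate landward coastal vectors to the nearest seaward direction.

    Affected nodes are (a) land nodes adjacent to sea and (b) sea nodes
    adjacent to land, in both cases only when the vector points toward
    land (its direction is closest to a land neighbour's direction).  The
    vector is rotated through the smallest angle that makes it point
    toward a sea neighbour; magnitudes are preserved and all other
    vectors are untouched.  A node needing correction with no sea
    neighbour has its vector zeroed (logged).
    """
    if mask.grid != field.grid:
        raise ValueError("mask grid does not match field grid")
    m = mask.mask
    nlat, nlon = field.grid.shape
    u1 = field.u1.copy()
    u2 = field.u2.copy()

    for i in range(nlat):
        for j in range(nlon):
            neigh = [
                (i + di, j + dj)
                for di, dj in _NEIGHBORS
                if 0 <= i + di < nlat and 0 <= j + dj < nlon
            ]
            sea = [(a, b) for a, b in neigh if not m[a, b]]
            land = [(a, b) for a, b in neigh if m[a, b]]
            if m[i, j]:
                if not sea:
                    continue  # inland node: untouched
            else:
                if not land:
                    continue  # open-sea node: untouched
            vx, vy = u1[i, j], u2[i, j]
            speed = math.hypot(vx, vy)
            if speed == 0.0:
                continue
            # direction the vector most nearly points along, among neighbours
            # (grid steps: lon ~ j, lat ~ i)
            best = max(
                neigh,
                key=lambda ab: (vx * (ab[1] - j) + vy * (ab[0] - i))
                / math.hypot(ab[1] - j, ab[0] - i),
            )
            if not m[best]:
                continue  # already points toward the sea
            if not sea:
                logger.warning(
                    "node (%d, %d): no sea neighbour, vector zeroed", i, j
                )
                u1[i, j] = 0.0
                u2[i, j] = 0.0
                continue
            # rotate to the sea-neighbour direction closest to the vector
            tgt = max(
                sea,
                key=lambda ab: (vx * (ab[1] - j) + vy * (ab[0] - i))
                / math.hypot(ab[1] - j, ab[0] - i),
            )
            d = math.hypot(tgt[1] - j, tgt[0] - i)
            u1[i, j] = speed * (tgt[1] - j) / d
            u2[i, j] = speed * (tgt[0] - i) / d
    return VelocityField(field.grid, u1, u2)


# -- ensemble and validation -------------------------------------------------


def build_ensemble(
    obs: Sequence[RawVelocityObs],
    cycles: Sequence[ProbeCycle],
    grid: Grid,
    mask: LandMask | None = None,
    n_fields: int = 500,
    config: AssimilationConfig = AssimilationConfig(),
    master_seed: int = 0,
    partition_label: str = "",
) -> FieldEnsemble:
    """Reconstruct an ensemble of fields from randomly thinned subsets.

    Member i thins the observations with a seed derived from
    (master_seed, i), interpolates an initial field, assimilates, and
    applies the land correction; the whole ensemble is deterministic
    given master_seed.  Subsets too small to triangulate are skipped and
    logged.
    """
    by_id = {o.cycle_id: c for o, c in zip(obs, cycles)}
    fields = []
    for i in range(n_fields):
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, i]))
        sub = thin_observations(obs, grid, rng)
        sub_cycles = [by_id[o.cycle_id] for o in sub]
        try:
            f0 = initial_field(sub, grid)
        except ValueError as exc:
            logger.warning("member %d skipped: %s", i, exc)
            continue
        f = assimilate(f0, sub, sub_cycles, config)
        if mask is not None:
            f = land_correct(f, mask)
        fields.append(f)
    return FieldEnsemble(
        fields=fields, partition_label=partition_label, master_seed=master_seed
    )


def prediction_error(
    field: VelocityField,
    cycles: Sequence[ProbeCycle],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float:
    """Median absolute endpoint error |y_obs - y_pred| in degrees."""
    if not cycles:
        raise ValueError("cannot compute prediction error on an empty cycle set")
    errs = []
    for c in cycles:
        pred = simulate_cycle(field, c, rtol=rtol, atol=atol)
        errs.append(
            math.hypot(
                pred.y_pred.lon - c.y_surface.lon, pred.y_pred.lat - c.y_surface.lat
            )
        )
    return float(np.median(errs))


def field_rms_error(field: VelocityField, evaluator) -> float:
    """RMS vector error of a gridded field against an analytic evaluator."""
    LON, LAT = field.grid.meshgrid()
    t1, t2 = evaluator(LON, LAT)
    return float(
        np.sqrt(np.mean((field.u1 - t1) ** 2 + (field.u2 - t2) ** 2))
    )
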