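"""Connectivity summaries of simulated larval cohorts.

Reduces trajectory cohorts and station tables to the study's summary
products: per-archipelago quantiles of great-circle displacement and
cumulative path length at the report times, pairwise separation
statistics between the known populations, and the probability that a
larva enters the habitat-compatible depth band (200-1600 m seafloor)
within a given drift time.  All distances are haversine great-circle
kilometres on a sphere of radius 6371 km.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .particle_tracking import Trajectory

EARTH_RADIUS_KM = 6371.0

#: Seafloor depth band (m) compatible with the recorded adult populations.
HABITAT_DEPTH_BAND_M = (200.0, 1600.0)


def great_circle_km(a, b) -> float | np.ndarray:
    """Haversine great-circle distance, km.  Accepts points or lon/lat arrays."""
    lon1, lat1 = np.radians(a[0]), np.radians(a[1])
    lon2, lat2 = np.radians(b[0]), np.radians(b[1])
    s = (
        np.sin(0.5 * (lat2 - lat1)) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin(0.5 * (lon2 - lon1)) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def _clamp_day(traj: Trajectory, t_days: int) -> int:
    return min(t_days, traj.n_days)


def distance_from_source(traj: Trajectory, t_days: int) -> float:
    """Great-circle displacement (km) from the day-0 release point.

    For a particle that left the domain before ``t_days`` the value at
    its last recorded day is used.
    """
    d = _clamp_day(traj, t_days)
    return great_circle_km(
        (traj.lons[0], traj.lats[0]), (traj.lons[d], traj.lats[d])
    )


def path_length(traj: Trajectory, t_days: int) -> float:
    """Cumulative daily-segment great-circle length (km) up to ``t_days``."""
    d = _clamp_day(traj, t_days)
    if d == 0:
        return 0.0
    seg = great_circle_km(
        (traj.lons[:d], traj.lats[:d]), (traj.lons[1 : d + 1], traj.lats[1 : d + 1])
    )
    return float(np.sum(seg))


def summarize_cohort(
    trajectories: Sequence[Trajectory],
    report_times: Sequence[int] = (50, 100, 250, 500),
    group: str = "",
) -> pd.DataFrame:
    """Median and 2.5/97.5 percentiles of displacement and path length.

    One row per report time; the 95% quantile interval is the
    2.5th-97.5th percentile range (linear interpolation).
    """
    if not trajectories:
        raise ValueError("empty cohort")
    rows = []
    for t in report_times:
        dist = np.array([distance_from_source(tr, t) for tr in trajectories])
        plen = np.array([path_length(tr, t) for tr in trajectories])
        rows.append(
            {
                "group": group,
                "t_days": t,
                "distance_median_km": np.median(dist),
                "distance_p2_5_km": np.percentile(dist, 2.5),
                "distance_p97_5_km": np.percentile(dist, 97.5),
                "path_median_km": np.median(plen),
                "path_p2_5_km": np.percentile(plen, 2.5),
                "path_p97_5_km": np.percentile(plen, 97.5),
            }
        )
    return pd.DataFrame(rows)


def separation_distances(stations) -> pd.DataFrame:
    """Pairwise great-circle separations between populations, by group pair.

    Rows cover every unordered group pair including within-group (the
    distinct-pair distances inside one group); a group with a single
    station yields a flagged, undefined within-group row.
    """
    groups: dict[str, list] = {}
    for st in stations:
        groups.setdefault(st.group, []).append(st.location)
    names = sorted(groups)
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i:]:
            if ga == gb:
                pts = groups[ga]
                if len(pts) < 2:
                    rows.append(
                        {
                            "group_a": ga, "group_b": gb,
                            "median_km": np.nan, "min_km": np.nan,
                            "max_km": np.nan, "n_pairs": 0, "defined": False,
                        }
                    )
                    continue
                d = [
                    great_circle_km(pts[p], pts[q])
                    for p in range(len(pts))
                    for q in range(p + 1, len(pts))
                ]
            else:
                d = [
                    great_circle_km(pa, pb)
                    for pa in groups[ga]
                    for pb in groups[gb]
                ]
            d = np.asarray(d)
            rows.append(
                {
                    "group_a": ga, "group_b": gb,
                    "median_km": float(np.median(d)),
                    "min_km": float(np.min(d)),
                    "max_km": float(np.max(d)),
                    "n_pairs": len(d), "defined": True,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegionMask:
    """Boolean raster over a regular lon/lat node grid (True = habitat)."""

    lons: np.ndarray
    lats: np.ndarray
    values: np.ndarray  # shape (n_lat, n_lon)

    def __post_init__(self):
        if self.values.shape != (len(self.lats), len(self.lons)):
            raise ValueError("mask shape does not match axes")

    def lookup(self, lon, lat) -> np.ndarray:
        """Nearest-cell mask value; points outside the raster are False."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        i = np.rint((lat - self.lats[0]) / (self.lats[1] - self.lats[0])).astype(int)
        j = np.rint((lon - self.lons[0]) / (self.lons[1] - self.lons[0])).astype(int)
        ok = (i >= 0) & (i < len(self.lats)) & (j >= 0) & (j < len(self.lons))
        out = np.zeros(lon.shape, dtype=bool)
        out[ok] = self.values[i[ok], j[ok]]
        return out


def habitat_mask(bathymetry, depth_band=HABITAT_DEPTH_BAND_M) -> RegionMask:
    """Cells whose seafloor depth lies within the band (inclusive).

    ``bathymetry`` carries node axes ``lons``/``lats`` and ``elevation``
    in the ETOPO convention (negative = metres below sea level).
    """
    lo, hi = depth_band
    depth = -np.asarray(bathymetry.elevation, dtype=float)
    return RegionMask(
        lons=np.asarray(bathymetry.lons),
        lats=np.asarray(bathymetry.lats),
        values=(depth >= lo) & (depth <= hi),
    )


def crossing_probability(
    trajectories: Sequence[Trajectory],
    mask: RegionMask,
    t_days: int,
) -> float:
    """Fraction of particles entering a habitat cell by whole day <= t_days.

    Positions are only sampled at whole days (the daily field-switching
    granularity), so sub-daily crossings are not interpolated.
    """
    if not trajectories:
        return 0.0
    n_hit = 0
    for tr in trajectories:
        d = _clamp_day(tr, t_days)
        if np.any(mask.lookup(tr.lons[: d + 1], tr.lats[: d + 1])):
            n_hit += 1
    return n_hit / len(trajectories)
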