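"""Persistence of field ensembles and cycle/station tables.

Ensembles are stored as classic netCDF (dimensions member, lat, lon;
variables u1, u2 and the land mask; attributes spacing, bounds, seed),
written through xarray's scipy backend.  A per-member CSV fallback is
provided for environments without any netCDF reader.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .grids import FieldEnsemble, Grid, LandMask, VelocityField
from .probe_data import RegionBounds


def ensemble_to_dataset(
    ensemble: FieldEnsemble, mask: LandMask | None = None
) -> xr.Dataset:
    grid = ensemble.grid
    u1 = np.stack([f.u1 for f in ensemble.fields])
    u2 = np.stack([f.u2 for f in ensemble.fields])
    data = {
        "u1": (("member", "lat", "lon"), u1),
        "u2": (("member", "lat", "lon"), u2),
    }
    if mask is not None:
        data["land"] = (("lat", "lon"), mask.mask.astype("i1"))
    ds = xr.Dataset(
        data,
        coords={
            "member": np.arange(len(ensemble)),
            "lat": grid.lats,
            "lon": grid.lons,
        },
        attrs={
            "spacing_deg": grid.spacing_deg,
            "lon_min": grid.bounds.lon_min,
            "lon_max": grid.bounds.lon_max,
            "lat_min": grid.bounds.lat_min,
            "lat_max": grid.bounds.lat_max,
            "master_seed": -1 if ensemble.master_seed is None else ensemble.master_seed,
            "partition_label": ensemble.partition_label,
        },
    )
    return ds


def save_ensemble(ensemble: FieldEnsemble, path, mask: LandMask | None = None):
    ensemble_to_dataset(ensemble, mask).to_netcdf(path, engine="scipy")


def load_ensemble(path) -> tuple[FieldEnsemble, LandMask | None]:
    ds = xr.open_dataset(path, engine="scipy")
    bounds = RegionBounds(
        float(ds.attrs["lon_min"]),
        float(ds.attrs["lon_max"]),
        float(ds.attrs["lat_min"]),
        float(ds.attrs["lat_max"]),
    )
    grid = Grid(bounds, spacing_deg=float(ds.attrs["spacing_deg"]))
    fields = [
        VelocityField(grid, ds["u1"].values[m], ds["u2"].values[m])
        for m in range(ds.sizes["member"])
    ]
    seed = int(ds.attrs.get("master_seed", -1))
    ens = FieldEnsemble(
        fields=fields,
        partition_label=str(ds.attrs.get("partition_label", "")),
        master_seed=None if seed < 0 else seed,
    )
    mask = None
    if "land" in ds:
        mask = LandMask(grid, ds["land"].values.astype(bool))
    return ens, mask


def save_ensemble_csv(ensemble: FieldEnsemble, directory):
    """CSV fallback: one file per member with node lon, lat, u1, u2."""
    import pathlib

    import pandas as pd

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    LON, LAT = ensemble.grid.meshgrid()
    for m, f in enumerate(ensemble.fields):
        pd.DataFrame(
            {
                "lon": LON.ravel(),
                "lat": LAT.ravel(),
                "u1": f.u1.ravel(),
                "u2": f.u2.ravel(),
            }
        ).to_csv(directory / f"member_{m:04d}.csv", index=False)
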