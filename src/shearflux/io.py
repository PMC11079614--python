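"""Readers and writers for gridded velocity fields and particle tracks.

Three field dialects are supported:

* ``netcdf`` — self-describing NetCDF (classic format via the scipy
  backend) with dims ``(t, y, x)`` and variables ``u, v, mask``;
* ``npz``    — a NumPy archive with the same arrays plus grid metadata;
* ``csv``    — long-form rows ``t,x,y,u,v`` (masked nodes carry NaN).

Units are CGS and are recorded in file metadata; nothing is converted
silently on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .fields import (
    FieldFormatError,
    Grid2D,
    GridSpacingError,
    ParticleTrackSet,
    VelocityField2D,
)

__all__ = [
    "read_velocity_field",
    "write_velocity_field",
    "read_tracks",
    "write_tracks",
]

_DIALECTS = ("netcdf", "npz", "csv")


def _check_uniform(coord: np.ndarray, name: str) -> float:
    d = np.diff(coord)
    if d.size == 0:
        raise GridSpacingError(f"{name} axis has a single node")
    step = float(np.mean(d))
    if step <= 0 or np.any(np.abs(d - step) > 1e-6 * abs(step)):
        raise GridSpacingError(f"non-uniform {name} spacing beyond 1e-6 tolerance")
    return step


def write_velocity_field(fld: VelocityField2D, path, dialect: str = "netcdf") -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    fld.validate()
    g = fld.grid
    if dialect == "netcdf":
        ds = xr.Dataset(
            data_vars=dict(
                u=(("t", "y", "x"), fld.u, {"units": "cm/s"}),
                v=(("t", "y", "x"), fld.v, {"units": "cm/s"}),
                mask=(("t", "y", "x"), fld.effective_mask().astype(np.int8)),
            ),
            coords=dict(
                t=("t", fld.times, {"units": "s"}),
                y=("y", g.y, {"units": "cm"}),
                x=("x", g.x, {"units": "cm"}),
            ),
            attrs={"units": "CGS (cm, s)", **{k: v for k, v in fld.attrs.items()
                                              if isinstance(v, (str, int, float))}},
        )
        ds.to_netcdf(path, engine="scipy")
    elif dialect == "npz":
        np.savez(
            path,
            u=fld.u,
            v=fld.v,
            mask=fld.effective_mask(),
            times=fld.times,
            x=g.x,
            y=g.y,
            units=np.array("CGS (cm, s)"),
        )
    else:  # csv
        X, Y = g.meshgrid()
        rows = []
        m = fld.effective_mask()
        for k, t in enumerate(fld.times):
            uu = np.where(m[k], fld.u[k], np.nan)
            vv = np.where(m[k], fld.v[k], np.nan)
            rows.append(
                pd.DataFrame(
                    {
                        "t": np.full(X.size, t),
                        "x": X.ravel(),
                        "y": Y.ravel(),
                        "u": uu.ravel(),
                        "v": vv.ravel(),
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def _field_from_arrays(x, y, times, u, v, mask, attrs=None) -> VelocityField2D:
    dx = _check_uniform(np.asarray(x, float), "x")
    dy = _check_uniform(np.asarray(y, float), "y")
    grid = Grid2D(nx=len(x), ny=len(y), dx=dx, dy=dy, x0=float(x[0]), y0=float(y[0]))
    return VelocityField2D(
        grid=grid, times=np.asarray(times, float), u=u, v=v,
        mask=None if mask is None else np.asarray(mask, bool),
        attrs=attrs or {},
    )


def read_velocity_field(path, dialect: str = "netcdf") -> VelocityField2D:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "netcdf":
        with xr.open_dataset(path, engine="scipy") as ds:
            for name in ("u", "v"):
                if name not in ds:
                    raise FieldFormatError(f"missing variable {name!r}")
            for name in ("t", "x", "y"):
                if name not in ds.coords:
                    raise FieldFormatError(f"missing coordinate {name!r}")
            mask = ds["mask"].values.astype(bool) if "mask" in ds else None
            return _field_from_arrays(
                ds["x"].values, ds["y"].values, ds["t"].values,
                ds["u"].values, ds["v"].values, mask,
                attrs=dict(ds.attrs),
            )
    if dialect == "npz":
        with np.load(path, allow_pickle=False) as z:
            for name in ("u", "v", "times", "x", "y"):
                if name not in z:
                    raise FieldFormatError(f"missing array {name!r}")
            mask = z["mask"].astype(bool) if "mask" in z else None
            return _field_from_arrays(z["x"], z["y"], z["times"], z["u"], z["v"], mask)
    # csv
    df = pd.read_csv(path)
    for name in ("t", "x", "y", "u", "v"):
        if name not in df.columns:
            raise FieldFormatError(f"missing column {name!r}")
    x = np.unique(df["x"].to_numpy())
    y = np.unique(df["y"].to_numpy())
    times = np.unique(df["t"].to_numpy())
    nx, ny, nt = x.size, y.size, times.size
    if len(df) != nx * ny * nt:
        # locate a hole for the error message
        full = pd.MultiIndex.from_product([times, y, x], names=["t", "y", "x"])
        have = pd.MultiIndex.from_arrays([df["t"], df["y"], df["x"]],
                                         names=["t", "y", "x"])
        missing = full.difference(have)
        where = missing[0] if len(missing) else "(duplicate rows)"
        raise FieldFormatError(f"incomplete grid: missing node (t, y, x) = {where}")
    df = df.sort_values(["t", "y", "x"], kind="mergesort")
    u = df["u"].to_numpy().reshape(nt, ny, nx)
    v = df["v"].to_numpy().reshape(nt, ny, nx)
    mask = np.isfinite(u) & np.isfinite(v)
    if mask.all():
        mask = None
    return _field_from_arrays(x, y, times, u, v, mask)


def write_tracks(tracks: ParticleTrackSet, path) -> None:
    tracks.data.to_csv(path, index=False)


def read_tracks(path) -> ParticleTrackSet:
    df = pd.read_csv(path)
    return ParticleTrackSet(df)
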