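"""Core gridded-field and particle-track containers.

All quantities are CGS (cm, s, g) throughout the package.  Velocity fields
live on a node-centered regular grid; the array layout is ``(n_times, ny,
nx)`` with ``x`` (cross-stream) along the last axis and ``y`` (streamwise)
along the middle axis.  Physical coordinates are ``x = x0 + i*dx``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Grid2D",
    "VelocityField2D",
    "ScalarField2D",
    "TensorField2D",
    "ParticleTrackSet",
    "FieldFormatError",
    "GridSpacingError",
    "crop",
    "superpose",
]


class FieldFormatError(ValueError):
    """Raised when an on-disk field or track table violates the format contract."""


class GridSpacingError(FieldFormatError):
    """Raised when grid coordinates are not uniformly spaced."""


@dataclass(frozen=True)
class Grid2D:
    """Regular node-centered 2D grid (cm)."""

    nx: int
    ny: int
    dx: float
    dy: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.nx < 4 or self.ny < 4:
            raise ValueError(f"grid must be at least 4x4, got {self.nx}x{self.ny}")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def x(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        return self.y0 + self.dy * np.arange(self.ny)

    @property
    def extent_x(self) -> float:
        return (self.nx - 1) * self.dx

    @property
    def extent_y(self) -> float:
        return (self.ny - 1) * self.dy

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of shape (ny, nx)."""
        return np.meshgrid(self.x, self.y, indexing="xy")

    def same_as(self, other: "Grid2D", tol: float = 1e-9) -> bool:
        return (
            self.nx == other.nx
            and self.ny == other.ny
            and abs(self.dx - other.dx) <= tol * self.dx
            and abs(self.dy - other.dy) <= tol * self.dy
            and abs(self.x0 - other.x0) <= tol * max(self.dx, 1.0)
            and abs(self.y0 - other.y0) <= tol * max(self.dy, 1.0)
        )


def _as_time_array(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    return t


def _as_frames(arr, grid: Grid2D, n_times: int, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim == 2:
        a = a[None, :, :]
    if a.shape != (n_times, grid.ny, grid.nx):
        raise ValueError(
            f"{name} has shape {a.shape}, expected {(n_times, grid.ny, grid.nx)}"
        )
    return a


@dataclass
class VelocityField2D:
    """Time-resolved (u, v) on a regular grid, with an optional validity mask.

    ``u`` is the cross-stream (x) component and ``v`` the streamwise (y)
    component, in cm/s.  Invalid nodes (e.g. a premasked swimmer body or
    unsupported interpolation nodes) carry ``mask == False`` and may hold
    NaN; valid nodes must be finite.
    """

    grid: Grid2D
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    mask: Optional[np.ndarray] = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _as_time_array(self.times)
        n = self.times.size
        self.u = _as_frames(self.u, self.grid, n, "u")
        self.v = _as_frames(self.v, self.grid, n, "v")
        if self.mask is not None:
            m = np.asarray(self.mask)
            if m.ndim == 2:
                m = m[None, :, :]
            if m.shape != self.u.shape:
                raise ValueError("mask shape must match velocity arrays")
            self.mask = m.astype(bool)
        self.validate()

    @property
    def n_times(self) -> int:
        return self.times.size

    def effective_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones_like(self.u, dtype=bool)
        return self.mask

    def validate(self) -> None:
        m = self.effective_mask()
        if not np.all(np.isfinite(self.u[m])) or not np.all(np.isfinite(self.v[m])):
            raise ValueError("non-finite velocity at unmasked nodes")

    def copy(self) -> "VelocityField2D":
        return VelocityField2D(
            grid=self.grid,
            times=self.times.copy(),
            u=self.u.copy(),
            v=self.v.copy(),
            mask=None if self.mask is None else self.mask.copy(),
            attrs=dict(self.attrs),
        )

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class ScalarField2D:
    """A scalar per grid node per frame (units context-dependent)."""

    grid: Grid2D
    times: np.ndarray
    values: np.ndarray
    mask: Optional[np.ndarray] = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _as_time_array(self.times)
        self.values = _as_frames(self.values, self.grid, self.times.size, "values")
        if self.mask is not None:
            m = np.asarray(self.mask)
            if m.ndim == 2:
                m = m[None, :, :]
            if m.shape != self.values.shape:
                raise ValueError("mask shape must match values")
            self.mask = m.astype(bool)

    def effective_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones_like(self.values, dtype=bool)
        return self.mask


@dataclass
class TensorField2D:
    """Symmetric 2x2 tensor per grid node per frame (3 stored components)."""

    grid: Grid2D
    times: np.ndarray
    txx: np.ndarray
    txy: np.ndarray
    tyy: np.ndarray
    mask: Optional[np.ndarray] = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _as_time_array(self.times)
        n = self.times.size
        self.txx = _as_frames(self.txx, self.grid, n, "txx")
        self.txy = _as_frames(self.txy, self.grid, n, "txy")
        self.tyy = _as_frames(self.tyy, self.grid, n, "tyy")
        if self.mask is not None:
            m = np.asarray(self.mask)
            if m.ndim == 2:
                m = m[None, :, :]
            if m.shape != self.txx.shape:
                raise ValueError("mask shape must match tensor components")
            self.mask = m.astype(bool)

    def effective_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones_like(self.txx, dtype=bool)
        return self.mask

    def trace(self) -> np.ndarray:
        return self.txx + self.tyy


_TRACK_COLUMNS = ["track_id", "t", "x", "y"]


@dataclass
class ParticleTrackSet:
    """Lagrangian tracer records emulating PTV output.

    Wraps a DataFrame with columns ``track_id, t, x, y`` and optionally
    ``u, v``; canonically sorted by ``(track_id, t)``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise FieldFormatError(f"track table missing columns: {missing}")
        df = df.sort_values(["track_id", "t"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(subset=["track_id", "t"])
        if dup.any():
            bad = df.loc[dup, "track_id"].iloc[0]
            raise FieldFormatError(f"duplicate (track_id, t) pair in track {bad}")
        for tid, g in df.groupby("track_id", sort=False):
            dt = np.diff(g["t"].to_numpy())
            if np.any(dt <= 0):
                raise FieldFormatError(f"non-monotone time within track {tid}")
        self.data = df

    @property
    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    @property
    def n_tracks(self) -> int:
        return self.track_ids.size

    def has_velocities(self) -> bool:
        return "u" in self.data.columns and "v" in self.data.columns

    def frame_times(self) -> np.ndarray:
        return np.unique(self.data["t"].to_numpy())

    def frame(self, t: float, atol: float = 1e-9) -> pd.DataFrame:
        sel = np.isclose(self.data["t"].to_numpy(), t, atol=atol, rtol=0)
        return self.data.loc[sel]


def crop(fld: VelocityField2D, x_range, y_range) -> VelocityField2D:
    """Restrict a field to the nodes inside ``x_range`` x ``y_range`` (cm).

    The sub-grid keeps the parent spacing; node selection is inclusive with
    a small tolerance, so a window of width W keeps floor(W/dx)+1 nodes when
    the window starts on a node.
    """
    g = fld.grid
    tolx, toly = 1e-9 * g.dx, 1e-9 * g.dy
    ix = np.where((g.x >= x_range[0] - tolx) & (g.x <= x_range[1] + tolx))[0]
    iy = np.where((g.y >= y_range[0] - toly) & (g.y <= y_range[1] + toly))[0]
    if ix.size == 0 or iy.size == 0:
        raise ValueError("crop window does not intersect the grid")
    if ix.size < 4 or iy.size < 4:
        raise ValueError("crop window keeps fewer than 4 nodes per axis")
    sub = Grid2D(
        nx=ix.size, ny=iy.size, dx=g.dx, dy=g.dy,
        x0=float(g.x[ix[0]]), y0=float(g.y[iy[0]]),
    )
    sl = np.ix_(np.arange(fld.n_times), iy, ix)
    return VelocityField2D(
        grid=sub,
        times=fld.times.copy(),
        u=fld.u[sl].copy(),
        v=fld.v[sl].copy(),
        mask=None if fld.mask is None else fld.mask[sl].copy(),
        attrs=dict(fld.attrs),
    )


def superpose(*flds: VelocityField2D) -> VelocityField2D:
    """Nodewise sum of velocity fields sharing one grid and time base."""
    if not flds:
        raise ValueError("superpose needs at least one field")
    first = flds[0]
    u = np.zeros_like(first.u)
    v = np.zeros_like(first.v)
    mask = None
    for f in flds:
        if not f.grid.same_as(first.grid):
            raise ValueError("superpose: grid mismatch")
        if f.n_times != first.n_times or not np.allclose(f.times, first.times):
            raise ValueError("superpose: time base mismatch")
        u = u + f.u
        v = v + f.v
        if f.mask is not None:
            mask = f.mask if mask is None else (mask & f.mask)
    if mask is not None:
        u = np.where(mask, u, np.nan)
        v = np.where(mask, v, np.nan)
    return VelocityField2D(grid=first.grid, times=first.times.copy(), u=u, v=v,
                           mask=mask, attrs={"units": "cm/s"})
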