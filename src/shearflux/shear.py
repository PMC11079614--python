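"""Large-scale shear diagnostics.

Profiles of the streamwise velocity component, the mean velocity gradient
P = <dv/dx> (spatiotemporal mean), its value normalized by a pure-shear
reference (P~, > 1 meaning the shear was intensified), and the rms
velocity.  Windows are ((x0, x1), (y0, y1)) in cm; ``None`` means the full
domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd

from .fields import VelocityField2D

__all__ = ["ShearDiagnostics", "v_profile", "mean_gradient",
           "normalized_gradient", "rms_velocity", "diagnose"]


def _window_indices(fld: VelocityField2D, window):
    g = fld.grid
    if window is None:
        return np.arange(g.nx), np.arange(g.ny)
    (xr0, xr1), (yr0, yr1) = window
    ix = np.where((g.x >= xr0 - 1e-9) & (g.x <= xr1 + 1e-9))[0]
    iy = np.where((g.y >= yr0 - 1e-9) & (g.y <= yr1 + 1e-9))[0]
    if ix.size == 0 or iy.size == 0:
        raise ValueError("window does not intersect the grid")
    return ix, iy


def v_profile(fld: VelocityField2D, window=None,
              frames: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Mean v(x): averaged over y and time, shifted so v(x=0) = 0.

    The shift interpolates linearly to x = 0 when it falls between nodes
    (profiles are left unshifted if x = 0 lies outside the window).
    Returns a DataFrame with columns ``x`` and ``v``.
    """
    ix, iy = _window_indices(fld, window)
    sel = fld.v[np.ix_(np.arange(fld.n_times) if frames is None else frames,
                       iy, ix)]
    m = fld.effective_mask()[np.ix_(
        np.arange(fld.n_times) if frames is None else frames, iy, ix)]
    with np.errstate(invalid="ignore"):
        prof = np.nanmean(np.where(m, sel, np.nan), axis=(0, 1))
    x = fld.grid.x[ix]
    if x[0] <= 0.0 <= x[-1]:
        prof = prof - np.interp(0.0, x, prof)
    return pd.DataFrame({"x": x, "v": prof})


def mean_gradient(fld: VelocityField2D, window=None, method: str = "centered",
                  frames: Optional[np.ndarray] = None) -> float:
    """P = <dv/dx>: the spatiotemporal mean velocity gradient (1/s).

    ``centered`` (default) averages centered differences of v over the
    window (equivalent to the endpoint secant for exactly linear data);
    ``lsq`` fits a least-squares slope to the y/time-averaged profile.
    """
    ix, iy = _window_indices(fld, window)
    if ix.size < 8:
        raise ValueError("window must span at least 8 x-nodes")
    if method == "lsq":
        prof = v_profile(fld, window, frames=frames)
        return float(np.polyfit(prof["x"], prof["v"], 1)[0])
    if method != "centered":
        raise ValueError(f"unknown gradient method {method!r}")
    kframes = np.arange(fld.n_times) if frames is None else frames
    v = fld.v[np.ix_(kframes, iy, ix)]
    m = fld.effective_mask()[np.ix_(kframes, iy, ix)]
    x = fld.grid.x[ix]
    grads = np.gradient(v, x, axis=2)
    with np.errstate(invalid="ignore"):
        return float(np.nanmean(np.where(m, grads, np.nan)))


def normalized_gradient(P_case: float, P_pure: float) -> float:
    """P~ = P_case / P_pure; > 1 means the shear was intensified."""
    if P_pure == 0:
        raise ValueError("pure-shear reference gradient is zero")
    return P_case / P_pure


def rms_velocity(fld: VelocityField2D, window=None,
                 frames: Optional[np.ndarray] = None) -> float:
    """Root-mean-square speed sqrt(<u^2 + v^2>) over the window and time."""
    ix, iy = _window_indices(fld, window)
    kframes = np.arange(fld.n_times) if frames is None else frames
    sl = np.ix_(kframes, iy, ix)
    m = fld.effective_mask()[sl]
    q = fld.u[sl] ** 2 + fld.v[sl] ** 2
    with np.errstate(invalid="ignore"):
        return float(np.sqrt(np.nanmean(np.where(m, q, np.nan))))


@dataclass
class ShearDiagnostics:
    """Bundle of shear diagnostics for one case."""

    label: str
    P: float
    u_rms: float
    window: Optional[tuple]
    n_frames: int
    P_tilde: Optional[float] = None
    profile: Optional[pd.DataFrame] = dc_field(default=None, repr=False)

    def to_row(self) -> dict:
        return {"case": self.label, "P": self.P, "P_tilde": self.P_tilde,
                "u_rms": self.u_rms, "n_frames": self.n_frames,
                "window": repr(self.window)}


def diagnose(fld: VelocityField2D, label: str = "", window=None,
             reference_P: Optional[float] = None,
             frames: Optional[np.ndarray] = None) -> ShearDiagnostics:
    """Compute profile, P, u_rms (and P~ if a reference is supplied)."""
    P = mean_gradient(fld, window, frames=frames)
    return ShearDiagnostics(
        label=label,
        P=P,
        u_rms=rms_velocity(fld, window, frames=frames),
        window=window,
        n_frames=fld.n_times if frames is None else len(frames),
        P_tilde=None if reference_P is None else normalized_gradient(P, reference_P),
        profile=v_profile(fld, window, frames=frames),
    )
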