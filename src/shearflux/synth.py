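"""Synthetic velocity fields and PTV emulation.

This module generates data with the statistical and geometric structure the
flux analysis assumes: a streamwise-uniform shear band (endpoint speeds
+/-1.2 cm/s across 7 cm by default, matching the laboratory flow the
package emulates), localized jets at controlled angles to the shear's
extensional strain eigenvector, intermittent on/off schedules, tracer
sampling at PTV-like densities, and scattered-to-grid reconstruction.

For a linear shear v(x) = gamma * x the rate-of-strain tensor is uniform
with extensional eigenvector at pi/4 to the x axis (gamma > 0).  A swimmer
propelling itself sheds a jet opposite to its swimming direction; the
angle theta_s between the swimming direction and the extensional
eigenvector is the geometric control parameter of the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator, griddata

from .fields import Grid2D, ParticleTrackSet, VelocityField2D, superpose
from .flux import fold_axial_angle

__all__ = [
    "ShearSpec",
    "JetSpec",
    "SwimmerEvent",
    "PTVConfig",
    "ScheduleSpec",
    "make_shear",
    "make_jet",
    "swimmer_field",
    "superpose",
    "solenoidal_projection",
    "emulate_ptv",
    "reconstruct_field",
    "stokes_number",
    "schedule_on_off",
]


@dataclass(frozen=True)
class ShearSpec:
    """Streamwise-uniform shear v(x); u = 0 everywhere.

    Specify either ``gamma`` (dv/dx, 1/s) or endpoint speed ``v_max``
    (cm/s) with full width ``width`` (cm); for the linear profile
    gamma = 2 v_max / width.  ``center`` is the x where v = 0.
    """

    gamma: Optional[float] = None
    v_max: Optional[float] = None
    width: Optional[float] = None
    profile: str = "linear"
    center: float = 0.0

    def __post_init__(self) -> None:
        if self.profile not in ("linear", "tanh"):
            raise ValueError(f"unknown shear profile {self.profile!r}")
        if self.gamma is None:
            if self.v_max is None or self.width is None:
                raise ValueError("give gamma, or v_max together with width")
            if self.width <= 0:
                raise ValueError("width must be positive")
            object.__setattr__(self, "gamma", 2.0 * self.v_max / self.width)
        if self.profile == "tanh" and self.width is None:
            raise ValueError("tanh profile needs a width")

    def v_of_x(self, x: np.ndarray) -> np.ndarray:
        xi = np.asarray(x, float) - self.center
        if self.profile == "linear":
            return self.gamma * xi
        # tanh ramp with matched central slope gamma
        half = self.width / 2.0
        return self.gamma * half * np.tanh(xi / half)

    def extensional_angle(self) -> float:
        """Orientation of the extensional strain eigenvector (from +x axis)."""
        return np.pi / 4.0 if self.gamma >= 0 else 3.0 * np.pi / 4.0


@dataclass(frozen=True)
class JetSpec:
    """A localized planar jet issuing from ``origin`` along ``axis_angle``.

    ``axis_angle`` is measured in radians from the +y (streamwise) axis,
    so a jet with axis_angle = 0 points downstream.  ``width`` is the
    nozzle width d (cm) and ``exit_speed`` the centerline exit speed U0
    (cm/s).  The default envelope conserves the momentum flux rho U0^2 d:
    the Gaussian cross-profile has half-width b(s) = b0 + beta*s with
    b0 = d/sqrt(pi), and the axial speed decays as sqrt(b0/b(s)).  Beyond
    ``extent`` the speed is smoothly cut below 1% of U0.
    """

    origin: tuple[float, float]
    axis_angle: float
    width: float
    exit_speed: float
    envelope: str = "gaussian-plume"
    spreading_rate: float = 0.11  # planar-jet half-width growth db/ds
    extent: Optional[float] = None  # cm; default 25 nozzle widths

    def __post_init__(self) -> None:
        if self.width <= 0 or self.exit_speed <= 0:
            raise ValueError("jet width and exit speed must be positive")
        if self.envelope not in ("gaussian-plume", "self-similar-planar"):
            raise ValueError(f"unknown jet envelope {self.envelope!r}")
        if self.extent is None:
            object.__setattr__(self, "extent", 25.0 * self.width)

    @property
    def direction(self) -> np.ndarray:
        """Unit vector of the jet axis (angle measured from +y)."""
        return np.array([np.sin(self.axis_angle), np.cos(self.axis_angle)])


@dataclass(frozen=True)
class SwimmerEvent:
    """A swimmer at ``position`` heading along ``swim_direction``.

    The induced jet points opposite the swimming direction.  ``theta_s``
    is the folded angle between the swimming direction and the shear's
    extensional strain eigenvector, in [0, pi/2]; it must be consistent
    with ``swim_direction`` (checked to 1e-9 by ``swimmer_field``).
    """

    position: tuple[float, float]
    swim_direction: tuple[float, float]
    theta_s: float

    def __post_init__(self) -> None:
        d = np.asarray(self.swim_direction, float)
        n = np.hypot(d[0], d[1])
        if n == 0:
            raise ValueError("swim_direction must be nonzero")
        object.__setattr__(self, "swim_direction", (float(d[0] / n), float(d[1] / n)))
        if not (0.0 <= self.theta_s <= np.pi / 2 + 1e-12):
            raise ValueError("theta_s must lie in [0, pi/2]")

    @classmethod
    def from_theta_s(cls, theta_s: float, shear: ShearSpec,
                     position=(0.0, 0.0), sign: int = +1) -> "SwimmerEvent":
        """Build an event whose swimming direction realizes ``theta_s``."""
        ang = shear.extensional_angle() + sign * theta_s
        return cls(position=tuple(position),
                   swim_direction=(float(np.cos(ang)), float(np.sin(ang))),
                   theta_s=theta_s)


@dataclass(frozen=True)
class PTVConfig:
    """Tracer sampling parameters emulating the PTV pipeline."""

    particles_per_frame: int = 9000
    frame_rate: float = 60.0  # 1/s
    position_noise_sd: float = 0.0  # cm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.particles_per_frame < 100:
            raise ValueError("need at least 100 particles per frame")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        if self.position_noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


@dataclass(frozen=True)
class ScheduleSpec:
    """Intermittent on/off schedule with exponentially jittered intervals."""

    mean_on_off_interval: float = 14.0  # s
    n_cycles: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_on_off_interval <= 0:
            raise ValueError("mean interval must be positive")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be nonnegative")


def make_shear(spec: ShearSpec, grid: Grid2D, times) -> VelocityField2D:
    """Streamwise-uniform shear: u = 0, v = v(x)."""
    t = np.atleast_1d(np.asarray(times, float))
    vx = spec.v_of_x(grid.x)
    v = np.broadcast_to(vx[None, None, :], (t.size, grid.ny, grid.nx)).copy()
    u = np.zeros_like(v)
    return VelocityField2D(grid=grid, times=t, u=u, v=v,
                           attrs={"units": "cm/s", "source": "shear"})


def _jet_uv(spec: JetSpec, X: np.ndarray, Y: np.ndarray):
    e = spec.direction
    px = X - spec.origin[0]
    py = Y - spec.origin[1]
    s = px * e[0] + py * e[1]          # along-axis coordinate
    r = -px * e[1] + py * e[0]         # cross-axis coordinate
    b0 = spec.width / np.sqrt(np.pi)
    b = b0 + spec.spreading_rate * np.maximum(s, 0.0)
    axial = np.sqrt(b0 / b)
    # upstream of the nozzle the speed drops off over one nozzle width
    axial = axial * np.exp(-0.5 * (np.minimum(s, 0.0) / b0) ** 2)
    speed = spec.exit_speed * axial * np.exp(-0.5 * (r / b) ** 2)
    # smooth far-field cutoff keeping the speed < 1% of U0 beyond `extent`
    rho = np.hypot(px, py)
    speed = speed * np.exp(-((rho / (0.62 * spec.extent)) ** 4))
    return speed * e[0], speed * e[1]


def make_jet(spec: JetSpec, grid: Grid2D, t=0.0, clean: bool = False) -> VelocityField2D:
    """Velocity field of a localized jet (one frame per requested time)."""
    if not (grid.x0 <= spec.origin[0] <= grid.x0 + grid.extent_x
            and grid.y0 <= spec.origin[1] <= grid.y0 + grid.extent_y):
        raise ValueError("jet origin outside the grid")
    times = np.atleast_1d(np.asarray(t, float))
    X, Y = grid.meshgrid()
    ju, jv = _jet_uv(spec, X, Y)
    u = np.broadcast_to(ju[None], (times.size, grid.ny, grid.nx)).copy()
    v = np.broadcast_to(jv[None], (times.size, grid.ny, grid.nx)).copy()
    attrs = {"units": "cm/s", "source": "jet"}
    tip = np.asarray(spec.origin) + spec.extent * spec.direction
    if not (grid.x0 <= tip[0] <= grid.x0 + grid.extent_x
            and grid.y0 <= tip[1] <= grid.y0 + grid.extent_y):
        attrs["jet_extent_exceeds_domain"] = True
    fld = VelocityField2D(grid=grid, times=times, u=u, v=v, attrs=attrs)
    if clean:
        fld = solenoidal_projection(fld)
    return fld


def solenoidal_projection(fld: VelocityField2D) -> VelocityField2D:
    """Project a field onto its divergence-free part (spectral Helmholtz).

    Solves for the potential part of the flow on the grid (treated as
    periodic) and removes it; intended for compact flows away from the
    boundary, where the periodic treatment is benign.
    """
    g = fld.grid
    kx = 2.0 * np.pi * np.fft.rfftfreq(g.nx, d=g.dx)
    ky = 2.0 * np.pi * np.fft.fftfreq(g.ny, d=g.dy)
    KX, KY = np.meshgrid(kx, ky, indexing="xy")
    k2 = KX**2 + KY**2
    k2[0, 0] = 1.0
    # spectral differentiation is ill-defined at the Nyquist modes of a
    # real field; drop them so the projected field is exactly solenoidal
    keep = np.ones_like(k2)
    if g.nx % 2 == 0:
        keep[:, -1] = 0.0
    if g.ny % 2 == 0:
        keep[g.ny // 2, :] = 0.0
    u = np.empty_like(fld.u)
    v = np.empty_like(fld.v)
    for k in range(fld.n_times):
        uh = np.fft.rfft2(fld.u[k]) * keep
        vh = np.fft.rfft2(fld.v[k]) * keep
        div = 1j * KX * uh + 1j * KY * vh
        phi = -div / k2  # laplacian(phi) = div u
        u[k] = np.fft.irfft2(uh - 1j * KX * phi, s=(g.ny, g.nx))
        v[k] = np.fft.irfft2(vh - 1j * KY * phi, s=(g.ny, g.nx))
    return VelocityField2D(grid=g, times=fld.times.copy(), u=u, v=v,
                           attrs={**fld.attrs, "solenoidal": True})


def swimmer_field(event: SwimmerEvent, shear: ShearSpec, grid: Grid2D,
                  t=0.0, jet_width: float = 0.3, jet_speed: float = 2.0,
                  clean: bool = False) -> VelocityField2D:
    """Superpose the background shear and the swimmer's wake jet.

    The jet is antiparallel to the swimming direction and anchored at the
    swimmer position.  The realized theta_s (folded angle between the
    swimming direction and the shear's extensional eigenvector) must match
    ``event.theta_s`` to 1e-9.
    """
    d = np.asarray(event.swim_direction, float)
    swim_angle = np.arctan2(d[1], d[0])
    realized = float(fold_axial_angle(swim_angle - shear.extensional_angle()))
    if abs(realized - event.theta_s) > 1e-9:
        raise ValueError(
            f"swim_direction realizes theta_s = {realized:.12f}, "
            f"event declares {event.theta_s:.12f}")
    # jet axis angle measured from +y: jet points along -swim_direction
    jet_dir = -d
    axis_angle = np.arctan2(jet_dir[0], jet_dir[1])
    jet = JetSpec(origin=tuple(event.position), axis_angle=float(axis_angle),
                  width=jet_width, exit_speed=jet_speed)
    times = np.atleast_1d(np.asarray(t, float))
    fld = superpose(make_shear(shear, grid, times),
                    make_jet(jet, grid, times, clean=clean))
    fld.attrs.update({"source": "swimmer", "theta_s": event.theta_s})
    return fld


def _field_interpolators(fld: VelocityField2D):
    """Space-time linear interpolators for (u, v); steady if single frame."""
    g = fld.grid
    if fld.n_times == 1:
        ui = RegularGridInterpolator((g.y, g.x), fld.u[0], bounds_error=False,
                                     fill_value=np.nan)
        vi = RegularGridInterpolator((g.y, g.x), fld.v[0], bounds_error=False,
                                     fill_value=np.nan)
        return (lambda t, pts: ui(pts)), (lambda t, pts: vi(pts))
    ui = RegularGridInterpolator((fld.times, g.y, g.x), fld.u,
                                 bounds_error=False, fill_value=np.nan)
    vi = RegularGridInterpolator((fld.times, g.y, g.x), fld.v,
                                 bounds_error=False, fill_value=np.nan)

    def at(interp):
        def f(t, pts):
            tp = np.column_stack([np.full(pts.shape[0], t), pts])
            return interp(tp)
        return f

    return at(ui), at(vi)


def emulate_ptv(fld: VelocityField2D, config: PTVConfig,
                duration: float) -> ParticleTrackSet:
    """Advect seeded tracers through the field and sample PTV-like tracks.

    Particles start uniformly over the domain, are advected with classical
    4-stage Runge-Kutta (frame interval subdivided by 4), sampled at the
    frame rate, and Gaussian position noise is added.  Velocities are
    attached by finite differences of the noisy positions (centered in the
    interior, one-sided at track ends).  Particles leaving the domain have
    their tracks truncated and are reseeded with fresh ids.
    """
    rng = np.random.default_rng(config.seed)
    g = fld.grid
    t0 = float(fld.times[0])
    if fld.n_times > 1 and t0 + duration > fld.times[-1] + 1e-9:
        raise ValueError("field does not cover the requested duration")
    n_frames = int(np.floor(duration * config.frame_rate)) + 1
    dt_frame = 1.0 / config.frame_rate
    n_sub = 4
    h = dt_frame / n_sub
    u_at, v_at = _field_interpolators(fld)
    xlim = (g.x0, g.x0 + g.extent_x)
    ylim = (g.y0, g.y0 + g.extent_y)

    n = config.particles_per_frame
    pos = np.column_stack([
        rng.uniform(*xlim, size=n),
        rng.uniform(*ylim, size=n),
    ])
    ids = np.arange(n)
    next_id = n

    rec_t, rec_id, rec_x, rec_y = [], [], [], []

    def record(t, ids_, pos_):
        rec_t.append(np.full(ids_.size, t))
        rec_id.append(ids_.copy())
        rec_x.append(pos_[:, 0].copy())
        rec_y.append(pos_[:, 1].copy())

    def vel(t, p):
        pts = np.column_stack([p[:, 1], p[:, 0]])  # (y, x) ordering
        u = u_at(t, pts)
        v = v_at(t, pts)
        return np.column_stack([np.nan_to_num(u), np.nan_to_num(v)])

    record(t0, ids, pos)
    t = t0
    for _ in range(n_frames - 1):
        for _ in range(n_sub):
            k1 = vel(t, pos)
            k2 = vel(t + h / 2, pos + h / 2 * k1)
            k3 = vel(t + h / 2, pos + h / 2 * k2)
            k4 = vel(t + h, pos + h * k3)
            pos = pos + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t = t + h
        # truncate exited particles and reseed replacements with new ids
        out = ((pos[:, 0] < xlim[0]) | (pos[:, 0] > xlim[1])
               | (pos[:, 1] < ylim[0]) | (pos[:, 1] > ylim[1]))
        n_out = int(out.sum())
        if n_out:
            pos[out, 0] = rng.uniform(*xlim, size=n_out)
            pos[out, 1] = rng.uniform(*ylim, size=n_out)
            ids = ids.copy()
            ids[out] = next_id + np.arange(n_out)
            next_id += n_out
        record(t, ids, pos)

    df = pd.DataFrame({
        "track_id": np.concatenate(rec_id),
        "t": np.concatenate(rec_t),
        "x": np.concatenate(rec_x),
        "y": np.concatenate(rec_y),
    })
    if config.position_noise_sd > 0:
        df["x"] += rng.normal(0.0, config.position_noise_sd, size=len(df))
        df["y"] += rng.normal(0.0, config.position_noise_sd, size=len(df))
    df = df.sort_values(["track_id", "t"], kind="mergesort").reset_index(drop=True)
    # velocities from finite differences of the (noisy) positions
    us, vs = np.empty(len(df)), np.empty(len(df))
    i0 = 0
    for tid, grp in df.groupby("track_id", sort=False):
        tt = grp["t"].to_numpy()
        n_g = len(grp)
        if n_g == 1:
            us[i0], vs[i0] = np.nan, np.nan
        else:
            us[i0:i0 + n_g] = np.gradient(grp["x"].to_numpy(), tt)
            vs[i0:i0 + n_g] = np.gradient(grp["y"].to_numpy(), tt)
        i0 += n_g
    df["u"], df["v"] = us, vs
    return ParticleTrackSet(df)


def reconstruct_field(tracks: ParticleTrackSet, grid: Grid2D,
                      method: str = "cubic",
                      min_samples: int = 50) -> VelocityField2D:
    """Scattered-to-grid interpolation of track velocities, per frame.

    Uses cubic (Clough-Tocher) interpolation by default, mirroring the
    gridding step of the laboratory pipeline.  Nodes outside the convex
    hull of the samples are masked; frames with fewer than ``min_samples``
    velocity samples are masked entirely with a warning.
    """
    if not tracks.has_velocities():
        raise ValueError("tracks carry no velocities to interpolate")
    times = tracks.frame_times()
    X, Y = grid.meshgrid()
    nt = times.size
    u = np.full((nt, grid.ny, grid.nx), np.nan)
    v = np.full((nt, grid.ny, grid.nx), np.nan)
    mask = np.zeros((nt, grid.ny, grid.nx), dtype=bool)
    for k, t in enumerate(times):
        fr = tracks.frame(t)
        fr = fr.dropna(subset=["u", "v"])
        if len(fr) < min_samples:
            warnings.warn(f"frame t = {t}: only {len(fr)} samples; frame masked")
            continue
        pts = fr[["x", "y"]].to_numpy()
        uk = griddata(pts, fr["u"].to_numpy(), (X, Y), method=method)
        vk = griddata(pts, fr["v"].to_numpy(), (X, Y), method=method)
        ok = np.isfinite(uk) & np.isfinite(vk)
        u[k] = np.where(ok, uk, np.nan)
        v[k] = np.where(ok, vk, np.nan)
        mask[k] = ok
    return VelocityField2D(grid=grid, times=times, u=u, v=v, mask=mask,
                           attrs={"units": "cm/s", "source": "ptv"})


def stokes_number(d_particle: float, rho_particle: float, rho_fluid: float,
                  nu_fluid: float, flow_timescale: float) -> float:
    """St = tau_p / tau_f with tau_p = rho_p d^2 / (18 rho_f nu_f).

    All CGS: d in cm, densities in g/cm^3, nu in cm^2/s, timescale in s.
    Small values (<< 1) mean the tracer follows the flow faithfully.
    """
    for name, val in [("d_particle", d_particle), ("rho_particle", rho_particle),
                      ("rho_fluid", rho_fluid), ("nu_fluid", nu_fluid),
                      ("flow_timescale", flow_timescale)]:
        if val <= 0:
            raise ValueError(f"{name} must be positive")
    tau_p = rho_particle * d_particle**2 / (18.0 * rho_fluid * nu_fluid)
    return tau_p / flow_timescale


def schedule_on_off(spec: ScheduleSpec) -> list[tuple[float, float]]:
    """Seeded on/off schedule: exponential intervals with the stated mean."""
    rng = np.random.default_rng(spec.seed)
    out = []
    t = 0.0
    for _ in range(spec.n_cycles):
        on = t + rng.exponential(spec.mean_on_off_interval)
        off = on + rng.exponential(spec.mean_on_off_interval)
        out.append((on, off))
        t = off
    return out
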