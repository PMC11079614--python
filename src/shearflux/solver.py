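"""Minimal quasi-2D incompressible solver (vorticity-streamfunction form).

Doubly periodic pseudo-spectral solver for

    d(omega)/dt + u . grad(omega) = nu laplacian(omega) - alpha omega + F,

with 2/3-rule dealiasing of the nonlinear term and exact integrating-factor
treatment of the viscous (nu k^2) and Rayleigh-friction (alpha) terms.
Linear friction is the large-scale energy sink of quasi-2D laboratory
flows: the dissipation it produces is proportional to the kinetic energy.

Forcing combines a Kolmogorov-type single-wavenumber body force that
drives a steady shear band v(x) with an optional schedulable angled-jet
momentum source (a compact Gaussian blob, ramped smoothly on and off),
standing in for swimmer agitation.  Velocities are recovered from the
streamfunction, so sampled fields are divergence-free to spectral
precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .fields import Grid2D, VelocityField2D
from .synth import ScheduleSpec, schedule_on_off

__all__ = [
    "SolverConfig",
    "JetForcing",
    "ForcingSpec",
    "SolverState",
    "step",
    "laminar_shear_state",
    "run_case",
    "run_geometry_experiment",
    "GeometryExperimentResult",
]


@dataclass(frozen=True)
class SolverConfig:
    """Grid, physical coefficients and time step of the spectral solver."""

    n: int = 128              # modes per side (power of two >= 32)
    domain_size: float = 10.0  # cm
    nu: float = 0.01          # cm^2/s
    alpha: float = 0.08       # 1/s, linear-friction rate
    dt: float = 0.01          # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 32 or (self.n & (self.n - 1)) != 0:
            raise ValueError("n must be a power of two >= 32")
        if self.nu < 0 or self.alpha < 0:
            raise ValueError("nu and alpha must be nonnegative")
        if self.dt <= 0 or self.domain_size <= 0:
            raise ValueError("dt and domain_size must be positive")

    @property
    def dx(self) -> float:
        return self.domain_size / self.n

    def grid(self) -> Grid2D:
        return Grid2D(nx=self.n, ny=self.n, dx=self.dx, dy=self.dx,
                      x0=-self.domain_size / 2.0, y0=0.0)


@dataclass(frozen=True)
class JetForcing:
    """Compact momentum source mimicking an angled jet.

    ``axis_angle`` is measured from the +y axis (like the dispensing
    needles); ``amplitude`` is the peak body force (cm/s^2); ``width`` the
    Gaussian blob scale (cm); ``schedule`` a list of (on, off) times and
    ``ramp`` the smooth on/off ramp duration (s).
    """

    origin: tuple[float, float]
    axis_angle: float
    width: float
    amplitude: float
    schedule: tuple = ()
    ramp: float = 0.1
    # separation of a force-free (pusher) dipole along the axis; 0 gives a
    # single momentum-injecting blob like a dispensing needle
    dipole_separation: float = 0.0

    def envelope(self, t: float) -> float:
        if not self.schedule:
            return 1.0
        env = 0.0
        for on, off in self.schedule:
            if on - self.ramp < t < off + self.ramp:
                up = np.clip((t - on) / self.ramp + 1.0, 0.0, 1.0)
                down = np.clip((off - t) / self.ramp + 1.0, 0.0, 1.0)
                env = max(env, float(up * down))
        return env


@dataclass(frozen=True)
class ForcingSpec:
    """Kolmogorov-type shear forcing plus an optional scheduled jet."""

    shear_amplitude: float = 0.0   # cm/s^2 peak body force along y
    shear_mode: int = 1            # wavenumber index of sin(2 pi m x / D)
    jet: Optional[JetForcing] = None


class _Operators:
    """Cached spectral operators for one (config, forcing) pair."""

    def __init__(self, config: SolverConfig, forcing: ForcingSpec):
        n = config.n
        d = config.domain_size
        self.config = config
        self.forcing = forcing
        # arrays are (ny, nx); rfft2 reduces the last (x) axis
        self.kx = 2.0 * np.pi * np.fft.rfftfreq(n, d=d / n)
        self.ky = 2.0 * np.pi * np.fft.fftfreq(n, d=d / n)
        self.KX, self.KY = np.meshgrid(self.kx, self.ky, indexing="xy")
        self.k2 = self.KX**2 + self.KY**2
        self.k2_inv = np.where(self.k2 > 0, 1.0 / np.where(self.k2 > 0, self.k2, 1.0), 0.0)
        kmax = np.pi * n / d
        self.dealias = ((np.abs(self.KX) <= (2.0 / 3.0) * kmax)
                        & (np.abs(self.KY) <= (2.0 / 3.0) * kmax))
        self.lin = config.nu * self.k2 + config.alpha
        grid = config.grid()
        self.X, self.Y = grid.meshgrid()
        # static vorticity forcing of the shear band:
        # F = (0, A sin(2 pi m x / D))  ->  curl = dFy/dx
        m = forcing.shear_mode
        kf = 2.0 * np.pi * m / d
        self.kf = kf
        fy = forcing.shear_amplitude * np.sin(kf * self.X)
        self.shear_curl_hat = self._curl_hat(np.zeros_like(fy), fy)
        self.jet_curl_hat = None
        if forcing.jet is not None:
            j = forcing.jet
            e = np.array([np.sin(j.axis_angle), np.cos(j.axis_angle)])

            def blob(center):
                r2 = (self.X - center[0])**2 + (self.Y - center[1])**2
                return j.amplitude * np.exp(-0.5 * r2 / j.width**2)

            if j.dipole_separation > 0:
                # force-free pusher: thrust ahead, reaction behind
                half = 0.5 * j.dipole_separation * e
                o = np.asarray(j.origin)
                g = blob(o + half) - blob(o - half)
            else:
                g = blob(j.origin)
            self.jet_curl_hat = self._curl_hat(g * e[0], g * e[1])

    def _curl_hat(self, fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
        return (1j * self.KX * np.fft.rfft2(fy)
                - 1j * self.KY * np.fft.rfft2(fx))

    def forcing_hat(self, t: float) -> np.ndarray:
        f = self.shear_curl_hat
        if self.jet_curl_hat is not None:
            env = self.forcing.jet.envelope(t)
            if env:
                f = f + env * self.jet_curl_hat
        return f

    def velocity_hat(self, w_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        psi_hat = w_hat * self.k2_inv      # omega = -laplacian(psi)
        u_hat = 1j * self.KY * psi_hat     # u = dpsi/dy
        v_hat = -1j * self.KX * psi_hat    # v = -dpsi/dx
        return u_hat, v_hat

    def nonlinear(self, w_hat: np.ndarray, t: float) -> np.ndarray:
        """-(u . grad omega) + forcing, dealiased, in spectral space."""
        wd = w_hat * self.dealias
        u_hat, v_hat = self.velocity_hat(wd)
        n = self.config.n
        u = np.fft.irfft2(u_hat, s=(n, n))
        v = np.fft.irfft2(v_hat, s=(n, n))
        wx = np.fft.irfft2(1j * self.KX * wd, s=(n, n))
        wy = np.fft.irfft2(1j * self.KY * wd, s=(n, n))
        adv = np.fft.rfft2(u * wx + v * wy) * self.dealias
        return -adv + self.forcing_hat(t)

    def energy(self, w_hat: np.ndarray) -> float:
        """Domain-mean kinetic energy (cm^2/s^2)."""
        u_hat, v_hat = self.velocity_hat(w_hat)
        n = self.config.n
        # Parseval for rfft2: double the reduced-axis modes except column 0
        weight = np.full(u_hat.shape, 2.0)
        weight[:, 0] = 1.0
        if n % 2 == 0:
            weight[:, -1] = 1.0
        e = 0.5 * np.sum(weight * (np.abs(u_hat)**2 + np.abs(v_hat)**2)) / n**4
        return float(e)

    def enstrophy(self, w_hat: np.ndarray) -> float:
        n = self.config.n
        weight = np.full(w_hat.shape, 2.0)
        weight[:, 0] = 1.0
        if n % 2 == 0:
            weight[:, -1] = 1.0
        return float(0.5 * np.sum(weight * np.abs(w_hat)**2) / n**4)

    def injection(self, w_hat: np.ndarray, t: float) -> float:
        """Energy injection rate by the body force, <u . F>."""
        u_hat, v_hat = self.velocity_hat(w_hat)
        f_hat = self.forcing_hat(t)
        fu_hat, fv_hat = self.velocity_hat(f_hat)  # F from its curl
        n = self.config.n
        weight = np.full(u_hat.shape, 2.0)
        weight[:, 0] = 1.0
        if n % 2 == 0:
            weight[:, -1] = 1.0
        inj = np.sum(weight * (u_hat.conj() * fu_hat
                               + v_hat.conj() * fv_hat).real) / n**4
        return float(inj)


@dataclass
class SolverState:
    """Vorticity in spectral (rfft2) space plus the current time."""

    w_hat: np.ndarray
    t: float = 0.0


_OPS_CACHE: dict = {}


def _ops(config: SolverConfig, forcing: ForcingSpec) -> _Operators:
    key = (config, forcing)
    ops = _OPS_CACHE.get(key)
    if ops is None:
        ops = _Operators(config, forcing)
        if len(_OPS_CACHE) > 8:
            _OPS_CACHE.clear()
        _OPS_CACHE[key] = ops
    return ops


def step(state: SolverState, config: SolverConfig, forcing: ForcingSpec,
         ops: Optional[_Operators] = None) -> SolverState:
    """Advance one time step with integrating-factor RK4.

    The viscous and friction terms are integrated exactly (a single mode
    with no nonlinearity decays by exp(-(nu k^2 + alpha) dt) per step);
    the dealiased nonlinear term and the forcing are handled by classical
    RK4.
    """
    if ops is None:
        ops = _ops(config, forcing)
    dt = config.dt
    w = state.w_hat
    t = state.t
    E1 = np.exp(-ops.lin * (dt / 2.0))
    E2 = E1 * E1
    k1 = ops.nonlinear(w, t)
    k2 = ops.nonlinear(E1 * (w + dt / 2.0 * k1), t + dt / 2.0)
    k3 = ops.nonlinear(E1 * w + dt / 2.0 * k2, t + dt / 2.0)
    k4 = ops.nonlinear(E2 * w + dt * E1 * k3, t + dt)
    w_new = (E2 * w + dt / 6.0 * (E2 * k1 + 2.0 * E1 * (k2 + k3) + k4))
    if not np.all(np.isfinite(w_new.view(float))):
        raise RuntimeError(
            f"solver produced non-finite vorticity at t = {t + dt:.4f} "
            f"(dt = {dt}, n = {config.n}); reduce dt or the forcing")
    return SolverState(w_hat=w_new, t=t + dt)


def laminar_shear_state(config: SolverConfig, forcing: ForcingSpec,
                        noise_amplitude: float = 0.0,
                        seed: Optional[int] = None) -> SolverState:
    """Analytic steady state of the shear forcing, plus optional seed noise.

    The single-mode Kolmogorov force F sin(k x) y-hat balances viscosity
    and friction at v(x) = F sin(k x) / (nu k^2 + alpha).
    """
    ops = _ops(config, forcing)
    denom = config.nu * ops.kf**2 + config.alpha
    v = forcing.shear_amplitude * np.sin(ops.kf * ops.X) / denom
    w_hat = 1j * ops.KX * np.fft.rfft2(v)  # omega = dv/dx for v(x)
    if noise_amplitude > 0:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        noise = rng.standard_normal((config.n, config.n))
        w_hat = w_hat + noise_amplitude * np.fft.rfft2(noise) * ops.dealias
        w_hat[0, 0] = 0.0
    return SolverState(w_hat=w_hat, t=0.0)


def run_case(config: SolverConfig, forcing: ForcingSpec, duration: float,
             sample_interval: Optional[float] = None,
             state: Optional[SolverState] = None,
             energy_bound: Optional[float] = None,
             sidecar_path=None) -> VelocityField2D:
    """Run the solver and sample velocity frames.

    Frames are sampled every ``sample_interval`` (default: 10 time steps).
    The returned field's ``attrs`` carry the config and an energy time
    series (kinetic energy, enstrophy, injection).  If the energy exceeds
    ``energy_bound`` the run aborts with a report.
    """
    ops = _ops(config, forcing)
    if state is None:
        state = SolverState(w_hat=np.zeros_like(ops.k2, dtype=complex), t=0.0)
    if sample_interval is None:
        sample_interval = 10 * config.dt
    every = max(1, int(round(sample_interval / config.dt)))
    n_steps = int(round(duration / config.dt))
    grid = config.grid()
    frames_u, frames_v, frame_t = [], [], []
    series = {"t": [], "energy": [], "enstrophy": [], "injection": []}

    def sample(st: SolverState):
        u_hat, v_hat = ops.velocity_hat(st.w_hat)
        n = config.n
        frames_u.append(np.fft.irfft2(u_hat, s=(n, n)))
        frames_v.append(np.fft.irfft2(v_hat, s=(n, n)))
        frame_t.append(st.t)
        series["t"].append(st.t)
        series["energy"].append(ops.energy(st.w_hat))
        series["enstrophy"].append(ops.enstrophy(st.w_hat))
        series["injection"].append(ops.injection(st.w_hat, st.t))

    sample(state)
    for i in range(1, n_steps + 1):
        state = step(state, config, forcing, ops)
        if i % every == 0 or i == n_steps:
            sample(state)
            if energy_bound is not None and series["energy"][-1] > energy_bound:
                raise RuntimeError(
                    f"energy {series['energy'][-1]:.3g} exceeded bound "
                    f"{energy_bound:.3g} at t = {state.t:.3f}")
    fld = VelocityField2D(grid=grid, times=np.asarray(frame_t),
                          u=np.asarray(frames_u), v=np.asarray(frames_v),
                          attrs={"units": "cm/s", "source": "solver",
                                 "config": {
                                     "n": config.n, "domain_size": config.domain_size,
                                     "nu": config.nu, "alpha": config.alpha,
                                     "dt": config.dt, "seed": config.seed},
                                 "energy_series": series})
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"config": fld.attrs["config"],
                       "energy_series": series}, fh, indent=1)
    return fld


@dataclass
class GeometryExperimentResult:
    """Paired jet/no-jet solver runs and the shear-modification diagnostic."""

    theta_s: float
    field_jet: VelocityField2D
    field_ref: VelocityField2D
    P_jet: float
    P_ref: float
    P_tilde: float
    window: tuple


def run_geometry_experiment(
    config: SolverConfig,
    base_forcing: ForcingSpec,
    theta_s: float,
    duration: float = 30.0,
    jet_amplitude: float = 0.2,
    jet_width: float = 0.5,
    mean_interval: float = 5.0,
    window_half_width: Optional[float] = None,
    noise_amplitude: float = 1e-6,
    reference_field: Optional[VelocityField2D] = None,
) -> GeometryExperimentResult:
    """Measure how an angled, intermittent jet modifies the mean shear.

    The shear band v(x) = V sin(2 pi x / D) has its steepest (most linear)
    gradient at x = 0, where the extensional strain eigenvector sits at
    pi/4 to the x axis.  A force-free jet dipole (swimmers exert no net
    force on the fluid) is forced at x = 0 at the angle realizing
    ``theta_s`` and pulsed on/off; a paired no-jet run from the same
    initial state provides the pure-shear reference.  The diagnostic is
    P~ = P_jet / P_ref with P = <dv/dx> averaged over the window and the
    measurement interval.
    """
    if not (0.0 <= theta_s <= np.pi / 2 + 1e-12):
        raise ValueError("theta_s must lie in [0, pi/2]")
    from .shear import mean_gradient  # local import to avoid a cycle

    d = config.domain_size
    if window_half_width is None:
        window_half_width = d / 8.0
    # jet axis: extensional eigenvector at pi/4 (from x), rotated by -theta_s
    axis_from_x = np.pi / 4.0 - theta_s
    axis_from_y = np.pi / 2.0 - axis_from_x
    schedule = tuple(schedule_on_off(ScheduleSpec(
        mean_on_off_interval=mean_interval, n_cycles=max(2, int(duration / mean_interval)),
        seed=config.seed + 101)))
    jet = JetForcing(origin=(0.0, d / 2.0), axis_angle=float(axis_from_y),
                     width=jet_width, amplitude=jet_amplitude,
                     schedule=schedule, ramp=0.2,
                     dipole_separation=1.5 * jet_width)
    forcing_jet = ForcingSpec(shear_amplitude=base_forcing.shear_amplitude,
                              shear_mode=base_forcing.shear_mode, jet=jet)
    init = laminar_shear_state(config, base_forcing,
                               noise_amplitude=noise_amplitude)
    init_ref = SolverState(w_hat=init.w_hat.copy(), t=0.0)
    fld_jet = run_case(config, forcing_jet, duration, state=init)
    if reference_field is not None:
        fld_ref = reference_field  # paired no-jet run shared across angles
    else:
        fld_ref = run_case(config, base_forcing, duration, state=init_ref)
    window = ((-window_half_width, window_half_width),
              (0.0, d))
    P_jet = mean_gradient(fld_jet, window)
    P_ref = mean_gradient(fld_ref, window)
    return GeometryExperimentResult(
        theta_s=theta_s, field_jet=fld_jet, field_ref=fld_ref,
        P_jet=P_jet, P_ref=P_ref, P_tilde=P_jet / P_ref, window=window)
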