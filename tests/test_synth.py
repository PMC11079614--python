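"""Synthetic shear/jet/swimmer fields, PTV emulation, schedules, tracers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shearflux import (Grid2D, JetSpec, PTVConfig, ParticleTrackSet,
                       ScheduleSpec, ShearSpec, SwimmerEvent, VelocityField2D,
                       emulate_ptv, make_jet, make_shear, reconstruct_field,
                       schedule_on_off, solenoidal_projection, stokes_number,
                       superpose, swimmer_field)
from shearflux.flux import fold_axial_angle

import pandas as pd


def test_make_shear_endpoints_and_symmetry(lab_grid, lab_shear):
    fld = make_shear(lab_shear, lab_grid, [0.0])
    assert np.all(fld.u == 0)
    # v is streamwise-uniform and hits +/-1.2 cm/s at the edges
    assert np.allclose(fld.v[0, :, -1], 1.2, atol=1e-12)
    assert np.allclose(fld.v[0, :, 0], -1.2, atol=1e-12)
    icenter = lab_grid.nx // 2
    assert np.allclose(fld.v[0, :, icenter], 0.0, atol=1e-12)
    # odd symmetry about the center
    np.testing.assert_allclose(fld.v[0, :, ::-1], -fld.v[0], atol=1e-12)
    # zero shear rate gives an identically zero field
    zero = make_shear(ShearSpec(gamma=0.0), lab_grid, [0.0])
    assert np.all(zero.v == 0)


def test_shear_spec_invariants():
    s = ShearSpec(v_max=1.2, width=7.0)
    assert s.gamma == pytest.approx(2 * 1.2 / 7.0)
    assert s.extensional_angle() == pytest.approx(np.pi / 4)
    assert ShearSpec(gamma=-0.3).extensional_angle() == pytest.approx(3 * np.pi / 4)
    with pytest.raises(ValueError):
        ShearSpec(v_max=1.0, width=-1.0)
    with pytest.raises(ValueError):
        ShearSpec()


def test_jet_geometry(lab_grid):
    spec = JetSpec(origin=(0.0, 0.0), axis_angle=np.pi / 4, width=0.3,
                   exit_speed=2.0, extent=3.0)
    fld = make_jet(spec, lab_grid, 0.0)
    speed = fld.speed()[0]
    jmax = np.unravel_index(np.argmax(speed), speed.shape)
    # peak speed at the nozzle (origin is a grid node)
    assert lab_grid.x[jmax[1]] == pytest.approx(0.0, abs=1e-9)
    assert lab_grid.y[jmax[0]] == pytest.approx(0.0, abs=1e-9)
    assert speed[jmax] == pytest.approx(2.0, rel=1e-9)
    # velocity is parallel to the axis direction everywhere it is nonzero
    e = spec.direction
    cross = fld.u[0] * e[1] - fld.v[0] * e[0]
    assert np.max(np.abs(cross)) < 1e-12
    # decays below 1% of U0 beyond the stated extent
    X, Y = lab_grid.meshgrid()
    far = np.hypot(X, Y) > spec.extent
    assert np.max(speed[far]) < 0.01 * spec.exit_speed


def test_jet_momentum_flux_matches_quadrature_oracle():
    # fine grid so the transect quadrature resolves the Gaussian profile
    spec = JetSpec(origin=(0.0, 0.0), axis_angle=0.0, width=0.3, exit_speed=2.0)
    g = Grid2D(nx=801, ny=401, dx=0.01, dy=0.01, x0=-4.0, y0=-0.5)
    fld = make_jet(spec, g, 0.0)
    iy = int(np.argmin(np.abs(g.y - 0.3)))  # transect 0.3 cm downstream
    flux = np.trapezoid(fld.u[0][iy] ** 2 + fld.v[0][iy] ** 2, g.x)
    assert flux == pytest.approx(spec.exit_speed**2 * spec.width, rel=0.02)


def test_jet_extent_warning_flag(small_grid):
    spec = JetSpec(origin=(2.4, 2.4), axis_angle=0.0, width=0.5, exit_speed=1.0)
    fld = make_jet(spec, small_grid, 0.0)  # extent far exceeds the 4.7 cm box
    assert fld.attrs.get("jet_extent_exceeds_domain")
    with pytest.raises(ValueError):
        make_jet(JetSpec(origin=(99.0, 0.0), axis_angle=0.0, width=0.5,
                         exit_speed=1.0), small_grid, 0.0)


def test_solenoidal_projection_removes_divergence(small_grid):
    spec = JetSpec(origin=(2.4, 2.4), axis_angle=0.3, width=0.4, exit_speed=1.5)
    raw = make_jet(spec, small_grid, 0.0)
    clean = solenoidal_projection(raw)
    kx = 2 * np.pi * np.fft.rfftfreq(small_grid.nx, small_grid.dx)
    ky = 2 * np.pi * np.fft.fftfreq(small_grid.ny, small_grid.dy)
    KX, KY = np.meshgrid(kx, ky, indexing="xy")

    def div(fld):
        return np.fft.irfft2(
            1j * KX * np.fft.rfft2(fld.u[0]) + 1j * KY * np.fft.rfft2(fld.v[0]),
            s=(small_grid.ny, small_grid.nx))

    rms_grad = np.sqrt(np.mean(div(raw) ** 2)) + 1e-30
    assert np.max(np.abs(div(clean))) < 1e-10 * max(1.0, np.max(np.abs(div(raw))))
    assert np.max(np.abs(div(clean))) < 1e-6 * rms_grad * small_grid.nx


def test_swimmer_theta_s_examples(lab_grid, lab_shear):
    times = [0.0]
    # swimming along the extensional eigenvector: theta_s = 0
    ev = SwimmerEvent.from_theta_s(0.0, lab_shear)
    d = np.asarray(ev.swim_direction)
    assert np.arctan2(d[1], d[0]) == pytest.approx(np.pi / 4)
    fld = swimmer_field(ev, lab_shear, lab_grid, times)
    assert fld.attrs["theta_s"] == 0.0
    # swimming along +x: theta_s = pi/4
    ev2 = SwimmerEvent(position=(0, 0), swim_direction=(1.0, 0.0),
                       theta_s=np.pi / 4)
    swimmer_field(ev2, lab_shear, lab_grid, times)
    # swimming along the compressional axis: theta_s = pi/2
    ev3 = SwimmerEvent(position=(0, 0),
                       swim_direction=(np.cos(3 * np.pi / 4), np.sin(3 * np.pi / 4)),
                       theta_s=np.pi / 2)
    swimmer_field(ev3, lab_shear, lab_grid, times)
    # inconsistent declaration is rejected
    bad = SwimmerEvent(position=(0, 0), swim_direction=(1.0, 0.0), theta_s=0.3)
    with pytest.raises(ValueError, match="theta_s"):
        swimmer_field(bad, lab_shear, lab_grid, times)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(angle=st.floats(-np.pi, np.pi))
def test_swimmer_realizes_theta_s_for_any_direction(angle):
    shear = ShearSpec(v_max=1.2, width=7.0)
    grid = Grid2D(nx=51, ny=51, dx=0.14, dy=0.14, x0=-3.5, y0=-3.5)
    direction = (np.cos(angle), np.sin(angle))
    theta_s = float(fold_axial_angle(angle - shear.extensional_angle()))
    ev = SwimmerEvent(position=(0, 0), swim_direction=direction, theta_s=theta_s)
    fld = swimmer_field(ev, shear, grid, [0.0])  # validates to 1e-9 internally
    assert fld.attrs["theta_s"] == pytest.approx(theta_s, abs=1e-9)


def test_superpose_algebra(small_grid):
    rng = np.random.default_rng(30)
    mk = lambda seed: VelocityField2D(
        grid=small_grid, times=[0.0],
        u=rng.standard_normal((1, 48, 48)), v=rng.standard_normal((1, 48, 48)))
    a, b, c = mk(0), mk(1), mk(2)
    zero = VelocityField2D(grid=small_grid, times=[0.0],
                           u=np.zeros((1, 48, 48)), v=np.zeros((1, 48, 48)))
    np.testing.assert_array_equal(superpose(a, zero).u, a.u)
    np.testing.assert_array_equal(superpose(a, b).u, superpose(b, a).u)
    np.testing.assert_allclose(superpose(superpose(a, b), c).u,
                               superpose(a, superpose(b, c)).u, atol=1e-12)


def test_ptv_zero_and_uniform_fields(small_grid):
    zeros = np.zeros((1, 48, 48))
    still = VelocityField2D(grid=small_grid, times=[0.0], u=zeros, v=zeros)
    cfg = PTVConfig(particles_per_frame=200, frame_rate=30.0,
                    position_noise_sd=0.0, seed=5)
    tracks = emulate_ptv(still, cfg, duration=0.2)
    for _, g in tracks.data.groupby("track_id"):
        assert g["x"].nunique() == 1 and g["y"].nunique() == 1
    # uniform flow: finite-difference velocities recover (U, 0)
    U = 0.8
    uni = VelocityField2D(grid=small_grid, times=[0.0],
                          u=np.full((1, 48, 48), U), v=zeros)
    tracks2 = emulate_ptv(uni, cfg, duration=0.2)
    # keep tracks that never came within one frame-step of the outflow
    # boundary (velocity samples are clipped outside the domain)
    margin = U / cfg.frame_rate + 1e-6
    xmax = small_grid.x0 + small_grid.extent_x
    far = tracks2.data.groupby("track_id")["x"].transform("max") < xmax - margin
    inside = tracks2.data[far].dropna(subset=["u"])
    assert len(inside) > 100
    np.testing.assert_allclose(inside["u"], U, atol=1e-9)
    np.testing.assert_allclose(inside["v"], 0.0, atol=1e-9)


def test_ptv_determinism(small_grid):
    u = np.zeros((1, 48, 48))
    fld = VelocityField2D(grid=small_grid, times=[0.0], u=u, v=u + 0.3)
    cfg = PTVConfig(particles_per_frame=150, frame_rate=30.0,
                    position_noise_sd=0.01, seed=9)
    t1 = emulate_ptv(fld, cfg, duration=0.1)
    t2 = emulate_ptv(fld, cfg, duration=0.1)
    pd.testing.assert_frame_equal(t1.data, t2.data)
    t3 = emulate_ptv(fld, PTVConfig(particles_per_frame=150, frame_rate=30.0,
                                    position_noise_sd=0.01, seed=10),
                     duration=0.1)
    assert not t3.data["x"].equals(t1.data["x"])


def test_reconstruction_exact_at_sample_nodes(small_grid):
    # velocities sampled exactly at grid nodes interpolate back exactly
    X, Y = small_grid.meshgrid()
    u = 0.3 * X - 0.1 * Y + 0.2 * np.sin(X)
    v = 0.5 * np.cos(Y) - 0.2 * X
    step = 3
    xs = X[::step, ::step].ravel()
    ys = Y[::step, ::step].ravel()
    df = pd.DataFrame({
        "track_id": np.arange(xs.size), "t": np.zeros(xs.size),
        "x": xs, "y": ys,
        "u": u[::step, ::step].ravel(), "v": v[::step, ::step].ravel(),
    })
    rec = reconstruct_field(ParticleTrackSet(df), small_grid)
    m = rec.effective_mask()[0]
    assert m[::step, ::step].all()
    np.testing.assert_allclose(rec.u[0][::step, ::step], u[::step, ::step],
                               atol=1e-10)


def test_reconstruction_masks_sparse_frames(small_grid):
    df = pd.DataFrame({
        "track_id": np.arange(10), "t": np.zeros(10),
        "x": np.linspace(0.2, 4.0, 10), "y": np.linspace(0.2, 4.0, 10),
        "u": np.ones(10), "v": np.ones(10),
    })
    with pytest.warns(UserWarning, match="masked"):
        rec = reconstruct_field(ParticleTrackSet(df), small_grid)
    assert not rec.effective_mask().any()


def test_stokes_number():
    # laboratory tracers: 115 um polyethylene spheres in 14% saltwater,
    # flow timescale set by the measured shear rate
    gamma = 2 * 1.2 / 7.0
    st_lab = stokes_number(d_particle=0.0115, rho_particle=1.025,
                           rho_fluid=1.1, nu_fluid=1.25e-2,
                           flow_timescale=1.0 / gamma)
    assert st_lab < 5e-3  # "of order 1e-3" or smaller
    # St scales with d^2
    s1 = stokes_number(0.01, 1.0, 1.0, 0.01, 1.0)
    s2 = stokes_number(0.02, 1.0, 1.0, 0.01, 1.0)
    assert s2 == pytest.approx(4 * s1)
    with pytest.raises(ValueError):
        stokes_number(-1.0, 1.0, 1.0, 0.01, 1.0)


def test_schedule_on_off():
    assert schedule_on_off(ScheduleSpec(mean_on_off_interval=14.0, n_cycles=0)) == []
    spec = ScheduleSpec(mean_on_off_interval=14.0, n_cycles=1000, seed=2)
    sched = schedule_on_off(spec)
    assert len(sched) == 1000
    times = np.array([0.0] + [t for pair in sched for t in pair])
    intervals = np.diff(times)
    assert np.all(intervals > 0)
    se = 14.0 / np.sqrt(intervals.size)
    assert abs(intervals.mean() - 14.0) < 3 * se
    assert schedule_on_off(spec) == sched  # same seed reproduces
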