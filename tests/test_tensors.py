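"""Stress tensors, decompositions, strain rate and eigenframes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shearflux import (FilterSpec, Grid2D, TensorField2D, VelocityField2D,
                       deviatoric, eigenframe, germano_decomposition,
                       leonard_cross_stresses, lowpass, sgs_reynolds_stress,
                       strain_rate, turbulent_stress)
from shearflux.filtering import interior_mask

from conftest import random_band_limited


def _field(grid, u, v):
    return VelocityField2D(grid=grid, times=[0.0], u=u[None], v=v[None])


def _tensor(grid, txx, txy, tyy):
    return TensorField2D(grid=grid, times=[0.0], txx=txx[None], txy=txy[None],
                         tyy=tyy[None])


def test_constant_field_gives_zero_stresses(small_grid):
    c = np.full((small_grid.ny, small_grid.nx), 1.7)
    fld = _field(small_grid, c, -0.5 * c)
    spec = FilterSpec(L=1.0)
    for T in (turbulent_stress(fld, spec), sgs_reynolds_stress(fld, spec),
              *leonard_cross_stresses(fld, spec),
              *germano_decomposition(fld, spec)):
        np.testing.assert_allclose(T.txx, 0.0, atol=1e-12)
        np.testing.assert_allclose(T.txy, 0.0, atol=1e-12)
        np.testing.assert_allclose(T.tyy, 0.0, atol=1e-12)


def test_pure_shear_stress_closed_form(lab_grid, lab_shear):
    # v = gamma x filtered with a gaussian gives tau_yy = gamma^2 sigma^2
    from shearflux import make_shear
    fld = make_shear(lab_shear, lab_grid, [0.0])
    spec = FilterSpec(L=1.0, kernel="gaussian", interior_margin=2.0)
    tau = turbulent_stress(fld, spec)
    im = interior_mask(lab_grid, spec)
    expected = lab_shear.gamma**2 * spec.sigma**2
    np.testing.assert_allclose(tau.tyy[0][im], expected, rtol=1e-6)
    np.testing.assert_allclose(tau.txx[0][im], 0.0, atol=1e-6 * expected)
    np.testing.assert_allclose(tau.txy[0][im], 0.0, atol=1e-6 * expected)


def test_classical_decomposition_identity(small_grid):
    u, v = random_band_limited(small_grid, seed=10)
    fld = _field(small_grid, u, v)
    spec = FilterSpec(L=1.0, kernel="gaussian", padding="mirror")
    tau = turbulent_stress(fld, spec)
    tauS = sgs_reynolds_stress(fld, spec)
    leo, cross = leonard_cross_stresses(fld, spec)
    scale = np.abs(tau.txx).max() + np.abs(tau.tyy).max() + 1e-30
    for comp in ("txx", "txy", "tyy"):
        lhs = getattr(tau, comp)
        rhs = (getattr(leo, comp) + getattr(cross, comp) + getattr(tauS, comp))
        np.testing.assert_allclose(lhs, rhs, atol=1e-12 * max(scale, 1.0))


def test_germano_sum_and_galilean_invariance(small_grid):
    u, v = random_band_limited(small_grid, seed=11)
    fld = _field(small_grid, u, v)
    shifted = _field(small_grid, u + 0.9, v - 0.4)
    spec = FilterSpec(L=1.0, kernel="gaussian", padding="periodic")
    tau = turbulent_stress(fld, spec)
    parts = germano_decomposition(fld, spec)
    parts_shift = germano_decomposition(shifted, spec)
    for comp in ("txx", "txy", "tyy"):
        total = sum(getattr(p, comp) for p in parts)
        np.testing.assert_allclose(total, getattr(tau, comp), atol=1e-12)
        # each Germano part is unchanged by a uniform velocity offset
        for p, ps in zip(parts, parts_shift):
            np.testing.assert_allclose(getattr(p, comp), getattr(ps, comp),
                                       atol=1e-10)
    # ... while the classical Leonard stress does change
    leo, _ = leonard_cross_stresses(fld, spec)
    leo_s, _ = leonard_cross_stresses(shifted, spec)
    assert np.max(np.abs(leo.txx - leo_s.txx)) > 1e-6


def test_sgs_stress_positive_semidefinite(small_grid):
    spec = FilterSpec(L=1.2, kernel="gaussian", padding="mirror")
    im = interior_mask(small_grid, spec)
    for seed in range(3):
        u, v = random_band_limited(small_grid, seed=seed, kmax_frac=0.6)
        tauS = sgs_reynolds_stress(_field(small_grid, u, v), spec)
        det = tauS.txx * tauS.tyy - tauS.txy**2
        norm = np.max(tauS.txx + tauS.tyy)
        assert np.all(tauS.txx[0][im] >= -1e-12 * norm)
        assert np.all(tauS.tyy[0][im] >= -1e-12 * norm)
        assert np.all(det[0][im] >= -1e-12 * norm**2)


def test_subcutoff_field_projector_limits(small_grid):
    # with all content at scales below the cutoff length, the residual is
    # the full field: tau_S = tau and Leonard/cross vanish
    rng = np.random.default_rng(12)
    spec_arr = np.zeros((small_grid.ny, small_grid.nx // 2 + 1), complex)
    kx = 2 * np.pi * np.fft.rfftfreq(small_grid.nx, small_grid.dx)
    ky = 2 * np.pi * np.fft.fftfreq(small_grid.ny, small_grid.dy)
    KX, KY = np.meshgrid(kx, ky, indexing="xy")
    kmag = np.hypot(KX, KY)
    band = (kmag > 9.0) & (kmag < 18.0)  # well above the cutoff pi/L = 1.96
    spec_arr[band] = (rng.standard_normal(band.sum())
                      + 1j * rng.standard_normal(band.sum()))
    u = np.fft.irfft2(spec_arr, s=(small_grid.ny, small_grid.nx))
    v = np.fft.irfft2(spec_arr * 1j, s=(small_grid.ny, small_grid.nx))
    u, v = u / np.abs(u).max(), v / np.abs(v).max()
    fld = _field(small_grid, u, v)
    spec = FilterSpec(L=1.6, kernel="sharp-spectral", padding="periodic")
    low = lowpass(fld, spec)
    assert np.max(np.abs(low.u)) < 1e-10  # content is entirely sub-filter
    tau = turbulent_stress(fld, spec)
    tauS = sgs_reynolds_stress(fld, spec)
    leo, cross = leonard_cross_stresses(fld, spec)
    np.testing.assert_allclose(tau.txx, tauS.txx, atol=1e-10)
    np.testing.assert_allclose(tau.txy, tauS.txy, atol=1e-10)
    np.testing.assert_allclose(leo.txx, 0.0, atol=1e-10)
    np.testing.assert_allclose(cross.txx, 0.0, atol=1e-10)


def test_strain_rate_linear_and_rotation(small_grid):
    X, Y = small_grid.meshgrid()
    gamma = 0.34
    S = strain_rate(_field(small_grid, np.zeros_like(X), gamma * X))
    np.testing.assert_allclose(S.txy, gamma / 2, atol=1e-12)
    np.testing.assert_allclose(S.txx, 0.0, atol=1e-12)
    np.testing.assert_allclose(S.tyy, 0.0, atol=1e-12)
    # rigid rotation has no strain
    Om = 0.8
    S2 = strain_rate(_field(small_grid, -Om * Y, Om * X))
    for comp in ("txx", "txy", "tyy"):
        np.testing.assert_allclose(getattr(S2, comp), 0.0, atol=1e-12)


def test_strain_trace_vanishes_for_solenoidal_field(small_grid):
    # spectral derivatives of a streamfunction-derived field are trace-free
    rng = np.random.default_rng(13)
    psi_hat = np.zeros((small_grid.ny, small_grid.nx // 2 + 1), complex)
    psi_hat[1:5, 1:5] = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
    kx = 2 * np.pi * np.fft.rfftfreq(small_grid.nx, small_grid.dx)
    ky = 2 * np.pi * np.fft.fftfreq(small_grid.ny, small_grid.dy)
    KX, KY = np.meshgrid(kx, ky, indexing="xy")
    u = np.fft.irfft2(1j * KY * psi_hat, s=(small_grid.ny, small_grid.nx))
    v = np.fft.irfft2(-1j * KX * psi_hat, s=(small_grid.ny, small_grid.nx))
    S = strain_rate(_field(small_grid, u, v), spectral=True)
    rms = np.sqrt(np.mean(S.txx**2 + 2 * S.txy**2 + S.tyy**2))
    assert np.max(np.abs(S.trace())) < 1e-8 * rms


def test_deviatoric(small_grid):
    ones = np.ones((small_grid.ny, small_grid.nx))
    iso = _tensor(small_grid, 2.0 * ones, 0.0 * ones, 2.0 * ones)
    dev = deviatoric(iso)
    np.testing.assert_allclose(dev.txx, 0.0, atol=1e-14)
    np.testing.assert_allclose(dev.tyy, 0.0, atol=1e-14)
    rng = np.random.default_rng(14)
    T = _tensor(small_grid, rng.standard_normal(ones.shape),
                rng.standard_normal(ones.shape), rng.standard_normal(ones.shape))
    np.testing.assert_allclose(deviatoric(T).trace(), 0.0, atol=1e-14)
    # traceless input is unchanged
    a, b = rng.standard_normal(ones.shape), rng.standard_normal(ones.shape)
    T0 = _tensor(small_grid, a, b, -a)
    np.testing.assert_allclose(deviatoric(T0).txx, a[None], atol=1e-14)


def test_eigenframe_special_cases(small_grid):
    ones = np.ones((small_grid.ny, small_grid.nx))
    # pure shear: extensional axis at exactly pi/4
    ef = eigenframe(_tensor(small_grid, 0 * ones, 0.5 * ones, 0 * ones))
    np.testing.assert_array_equal(ef.angle, np.pi / 4)
    # diag(a, -a): extensional axis along x, lambda = a
    ef2 = eigenframe(_tensor(small_grid, 2.0 * ones, 0 * ones, -2.0 * ones))
    np.testing.assert_array_equal(ef2.angle, 0.0)
    np.testing.assert_allclose(ef2.lambda_max, 2.0)
    # isotropic tensor: degenerate, flagged not oriented
    ef3 = eigenframe(_tensor(small_grid, ones, 0 * ones, ones))
    assert np.all(ef3.degenerate())


@settings(deadline=None, derandomize=True, max_examples=100)
@given(a=st.floats(-5, 5), b=st.floats(-5, 5),
       phi=st.floats(0, np.pi))
def test_eigenframe_rotation_equivariance(a, b, phi):
    """Rotating a tensor rotates its recovered eigen-angle (mod pi)."""
    lam = np.hypot(a, b)
    if lam < 1e-6:
        return
    g = Grid2D(nx=4, ny=4, dx=1.0, dy=1.0)
    ones = np.ones((4, 4))
    # R T R^T for traceless symmetric T: (a, b) rotates at twice the angle
    c2, s2 = np.cos(2 * phi), np.sin(2 * phi)
    txx = a * c2 - b * s2
    txy = a * s2 + b * c2
    base = eigenframe(TensorField2D(grid=g, times=[0.0], txx=a * ones[None],
                                    txy=b * ones[None], tyy=-a * ones[None]))
    rot = eigenframe(TensorField2D(grid=g, times=[0.0], txx=txx * ones[None],
                                   txy=txy * ones[None], tyy=-txx * ones[None]))
    d = (rot.angle[0, 0, 0] - base.angle[0, 0, 0] - phi) % np.pi
    assert min(d, np.pi - d) < 1e-10
    assert abs(rot.lambda_max[0, 0, 0] - lam) < 1e-10 * max(lam, 1)
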