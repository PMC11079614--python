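"""Turbulent stress tensors, their decompositions, strain rate and eigenframes.

The turbulent stress at filter scale L is

    tau_ij(L) = (u_i u_j)^(L) - u_i^(L) u_j^(L),

the stress exerted by sub-L motions on the resolved flow.  It splits
exactly into Leonard, cross and subgrid-scale Reynolds parts,

    tau = Leonard + cross + tau_S,
    tau_S,ij(L) = ((u_i - u_i^(L)) (u_j - u_j^(L)))^(L),

and, alternatively, into the Galilean-invariant generalized-central-moment
(Germano) parts.  The rate-of-strain tensor of the filtered field is
S_ij(L) = (du_i^(L)/dx_j + du_j^(L)/dx_i)/2.  In 2D the deviatoric part of
any symmetric tensor has eigenvalues +/- lambda; the orientation of the
extensional eigenvector (largest eigenvalue) is an axial angle in [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import Grid2D, TensorField2D, VelocityField2D
from .filtering import FilterSpec, filtered_product, lowpass, residual

__all__ = [
    "EigenFrameField",
    "turbulent_stress",
    "sgs_reynolds_stress",
    "leonard_cross_stresses",
    "germano_decomposition",
    "strain_rate",
    "deviatoric",
    "eigenframe",
]

DEGENERACY_RTOL = 1e-12


def _fp(a: np.ndarray, b: np.ndarray, fld: VelocityField2D, spec: FilterSpec,
        mask=None) -> np.ndarray:
    """Filtered product of two component arrays on the field's grid."""
    out = filtered_product(a, b, spec=spec, grid=fld.grid, times=fld.times,
                           mask=mask)
    return out.values


def _combine_mask(*masks):
    out = None
    for m in masks:
        if m is not None:
            out = m if out is None else (out & m)
    return out


def turbulent_stress(fld: VelocityField2D, spec: FilterSpec) -> TensorField2D:
    """tau_ij(L) = (u_i u_j)^(L) - u_i^(L) u_j^(L)."""
    low = lowpass(fld, spec)
    m = fld.mask
    txx = _fp(fld.u, fld.u, fld, spec, m) - low.u * low.u
    txy = _fp(fld.u, fld.v, fld, spec, m) - low.u * low.v
    tyy = _fp(fld.v, fld.v, fld, spec, m) - low.v * low.v
    return TensorField2D(grid=fld.grid, times=fld.times.copy(),
                         txx=txx, txy=txy, tyy=tyy, mask=low.mask,
                         attrs={**spec.meta(), "tensor": "tau"})


def sgs_reynolds_stress(fld: VelocityField2D, spec: FilterSpec) -> TensorField2D:
    """tau_S,ij(L): the filtered outer product of sub-filter velocities."""
    res = residual(fld, spec)
    m = fld.mask
    ru = np.where(res.effective_mask(), res.u, 0.0)
    rv = np.where(res.effective_mask(), res.v, 0.0)
    txx = _fp(ru, ru, fld, spec, m)
    txy = _fp(ru, rv, fld, spec, m)
    tyy = _fp(rv, rv, fld, spec, m)
    return TensorField2D(grid=fld.grid, times=fld.times.copy(),
                         txx=txx, txy=txy, tyy=tyy, mask=res.mask,
                         attrs={**spec.meta(), "tensor": "tau_S"})


def leonard_cross_stresses(
    fld: VelocityField2D, spec: FilterSpec
) -> tuple[TensorField2D, TensorField2D]:
    """Classical Leonard and cross stresses.

    Leonard_ij = (ubar_i ubar_j)^(L) - ubar_i ubar_j,
    Cross_ij   = (ubar_i u'_j)^(L) + (u'_i ubar_j)^(L),

    so that tau = Leonard + Cross + tau_S holds nodewise by construction.
    """
    low = lowpass(fld, spec)
    res = residual(fld, spec)
    m = fld.mask
    bu, bv = low.u, low.v
    ru = np.where(res.effective_mask(), res.u, 0.0)
    rv = np.where(res.effective_mask(), res.v, 0.0)
    lxx = _fp(bu, bu, fld, spec, m) - bu * bu
    lxy = _fp(bu, bv, fld, spec, m) - bu * bv
    lyy = _fp(bv, bv, fld, spec, m) - bv * bv
    cxx = 2.0 * _fp(bu, ru, fld, spec, m)
    cxy = _fp(bu, rv, fld, spec, m) + _fp(ru, bv, fld, spec, m)
    cyy = 2.0 * _fp(bv, rv, fld, spec, m)
    leonard = TensorField2D(grid=fld.grid, times=fld.times.copy(),
                            txx=lxx, txy=lxy, tyy=lyy, mask=low.mask,
                            attrs={**spec.meta(), "tensor": "leonard"})
    cross = TensorField2D(grid=fld.grid, times=fld.times.copy(),
                          txx=cxx, txy=cxy, tyy=cyy, mask=low.mask,
                          attrs={**spec.meta(), "tensor": "cross"})
    return leonard, cross


def germano_decomposition(
    fld: VelocityField2D, spec: FilterSpec
) -> tuple[TensorField2D, TensorField2D, TensorField2D]:
    """Generalized-central-moment (Galilean-invariant) decomposition.

    Each part is a central moment of the pair of fields involved:

    Leonard_G_ij = (ubar_i ubar_j)^(L) - ubar_i^(L) ubar_j^(L)
    Cross_G_ij   = (ubar_i u'_j + u'_i ubar_j)^(L)
                   - ubar_i^(L) u'_j^(L) - u'_i^(L) ubar_j^(L)
    Reyn_G_ij    = (u'_i u'_j)^(L) - u'_i^(L) u'_j^(L)

    The three parts again sum exactly to tau.
    """
    low = lowpass(fld, spec)
    res = residual(fld, spec)
    m = fld.mask
    bu, bv = low.u, low.v
    ru = np.where(res.effective_mask(), res.u, 0.0)
    rv = np.where(res.effective_mask(), res.v, 0.0)
    low2 = lowpass(low, spec)
    res_low = lowpass(
        VelocityField2D(grid=fld.grid, times=fld.times.copy(), u=ru, v=rv,
                        mask=fld.mask), spec)
    bbu, bbv = low2.u, low2.v
    rlu, rlv = res_low.u, res_low.v

    def central(a, b, fa, fb):
        return _fp(a, b, fld, spec, m) - fa * fb

    lxx = central(bu, bu, bbu, bbu)
    lxy = central(bu, bv, bbu, bbv)
    lyy = central(bv, bv, bbv, bbv)
    cxx = 2.0 * central(bu, ru, bbu, rlu)
    cxy = (central(bu, rv, bbu, rlv) + central(ru, bv, rlu, bbv))
    cyy = 2.0 * central(bv, rv, bbv, rlv)
    rxx = central(ru, ru, rlu, rlu)
    rxy = central(ru, rv, rlu, rlv)
    ryy = central(rv, rv, rlv, rlv)
    mask = _combine_mask(low.mask, low2.mask, res_low.mask)
    mk = dict(spec.meta())
    t = fld.times.copy()
    return (
        TensorField2D(grid=fld.grid, times=t, txx=lxx, txy=lxy, tyy=lyy,
                      mask=mask, attrs={**mk, "tensor": "leonard_germano"}),
        TensorField2D(grid=fld.grid, times=t, txx=cxx, txy=cxy, tyy=cyy,
                      mask=mask, attrs={**mk, "tensor": "cross_germano"}),
        TensorField2D(grid=fld.grid, times=t, txx=rxx, txy=rxy, tyy=ryy,
                      mask=mask, attrs={**mk, "tensor": "reynolds_germano"}),
    )


def strain_rate(filtered: VelocityField2D, spectral: bool = False) -> TensorField2D:
    """Rate-of-strain tensor of a (filtered) velocity field (1/s).

    Derivatives are 2nd-order centered differences in the interior and
    one-sided at the edges (exact for linear fields), so the same code path
    serves non-periodic PTV-like fields and solver output.  ``spectral=True``
    switches to FFT derivatives (periodic fields only).
    """
    g = filtered.grid
    n = filtered.n_times
    sxx = np.empty_like(filtered.u)
    syy = np.empty_like(filtered.u)
    sxy = np.empty_like(filtered.u)
    for k in range(n):
        if spectral:
            kx = 2.0 * np.pi * np.fft.rfftfreq(g.nx, d=g.dx)
            ky = 2.0 * np.pi * np.fft.fftfreq(g.ny, d=g.dy)
            KX, KY = np.meshgrid(kx, ky, indexing="xy")

            def ddx(a):
                return np.fft.irfft2(1j * KX * np.fft.rfft2(a), s=a.shape)

            def ddy(a):
                return np.fft.irfft2(1j * KY * np.fft.rfft2(a), s=a.shape)

            dudx, dudy = ddx(filtered.u[k]), ddy(filtered.u[k])
            dvdx, dvdy = ddx(filtered.v[k]), ddy(filtered.v[k])
        else:
            dudy, dudx = np.gradient(filtered.u[k], g.dy, g.dx)
            dvdy, dvdx = np.gradient(filtered.v[k], g.dy, g.dx)
        sxx[k] = dudx
        syy[k] = dvdy
        sxy[k] = 0.5 * (dudy + dvdx)
    return TensorField2D(grid=g, times=filtered.times.copy(),
                         txx=sxx, txy=sxy, tyy=syy, mask=filtered.mask,
                         attrs={**filtered.attrs, "tensor": "strain_rate"})


def deviatoric(T: TensorField2D) -> TensorField2D:
    """Remove the isotropic part: T - (tr T / 2) I."""
    half_tr = 0.5 * (T.txx + T.tyy)
    return TensorField2D(grid=T.grid, times=T.times.copy(),
                         txx=T.txx - half_tr, txy=T.txy.copy(),
                         tyy=T.tyy - half_tr, mask=T.mask,
                         attrs={**T.attrs, "deviatoric": True})


@dataclass
class EigenFrameField:
    """Largest deviatoric eigenvalue and extensional-eigenvector angle.

    ``angle`` is axial, in [0, pi) measured from the +x axis, and is NaN at
    degenerate nodes (deviatoric part indistinguishable from zero); those
    nodes are excluded from alignment statistics downstream.
    """

    grid: Grid2D
    times: np.ndarray
    lambda_max: np.ndarray
    angle: np.ndarray
    attrs: dict = dc_field(default_factory=dict)

    def degenerate(self) -> np.ndarray:
        return ~np.isfinite(self.angle)


def eigenframe(T: TensorField2D) -> EigenFrameField:
    """Eigenframe of the deviatoric part of a symmetric tensor field.

    For deviatoric [[a, b], [b, -a]] the eigenvalues are +/- sqrt(a^2+b^2)
    and the extensional eigenvector sits at angle atan2(b, a)/2.
    """
    a = T.txx - 0.5 * (T.txx + T.tyy)
    b = T.txy
    lam = np.hypot(a, b)
    angle = 0.5 * np.arctan2(b, a)
    angle = np.mod(angle, np.pi)
    scale = np.sqrt(np.nanmean(
        np.where(T.effective_mask(), T.txx**2 + 2 * T.txy**2 + T.tyy**2, np.nan)))
    if not np.isfinite(scale):
        scale = 0.0
    degenerate = lam <= DEGENERACY_RTOL * max(scale, np.finfo(float).tiny)
    angle = np.where(degenerate, np.nan, angle)
    if T.mask is not None:
        angle = np.where(T.mask, angle, np.nan)
    return EigenFrameField(grid=T.grid, times=T.times.copy(),
                           lambda_max=lam, angle=angle, attrs=dict(T.attrs))
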