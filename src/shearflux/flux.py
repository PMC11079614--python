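"""Spectral energy flux through filter scale L and its tensor-geometry form.

The pointwise flux is the stress working against the filtered rate of
strain,

    Q(L) = -tau_ij(L) S_ij(L),

with Q < 0 meaning inverse flux (energy toward larger scales) and Q > 0
forward flux (toward smaller scales).  For incompressible 2D flow this is
equivalent to the eigenframe form

    Q(L) = -2 lambda_tau lambda_S cos(2 theta),

where lambda_tau, lambda_S are the largest deviatoric eigenvalues and
theta in [0, pi/2] is the folded angle between the extensional
eigenvectors; cos(2 theta) acts as the efficiency of the transfer.  The
net flux reported by default is Q_s, built from the subgrid-scale Reynolds
stress, which dominates the net transfer and is free of the near-boundary
contamination the Leonard and cross terms suffer from.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fields import Grid2D, ScalarField2D, TensorField2D, VelocityField2D
from .filtering import FilterSpec, interior_mask, lowpass
from .tensors import (EigenFrameField, deviatoric, eigenframe,
                      sgs_reynolds_stress, strain_rate, turbulent_stress)

__all__ = [
    "FluxCurve",
    "GeometryField",
    "flux_pointwise",
    "sgs_flux_pointwise",
    "flux_from_geometry",
    "alignment_angle",
    "net_flux_curve",
    "classify_theta_s",
    "fold_axial_angle",
    "effective_viscosity",
]


def _check_meta(tau: TensorField2D, S: TensorField2D) -> None:
    if not tau.grid.same_as(S.grid):
        raise ValueError("flux: grid mismatch between stress and strain")
    for key in ("filter_L", "filter_kernel"):
        a, b = tau.attrs.get(key), S.attrs.get(key)
        if a is not None and b is not None and a != b:
            raise ValueError(f"flux: {key} mismatch ({a!r} vs {b!r})")


def _contract(tau: TensorField2D, S: TensorField2D) -> np.ndarray:
    return tau.txx * S.txx + 2.0 * tau.txy * S.txy + tau.tyy * S.tyy


def flux_pointwise(tau: TensorField2D, S: TensorField2D) -> ScalarField2D:
    """Q(L) = -tau_ij S_ij per node (cm^2/s^3)."""
    _check_meta(tau, S)
    q = -_contract(tau, S)
    mask = None
    if tau.mask is not None or S.mask is not None:
        mask = tau.effective_mask() & S.effective_mask()
    return ScalarField2D(grid=tau.grid, times=tau.times.copy(), values=q,
                         mask=mask, attrs={**tau.attrs, "quantity": "Q"})


def sgs_flux_pointwise(tauS: TensorField2D, S: TensorField2D) -> ScalarField2D:
    """Q_s(L) = -tau_S,ij S_ij per node (cm^2/s^3)."""
    out = flux_pointwise(tauS, S)
    out.attrs["quantity"] = "Qs"
    return out


def flux_from_geometry(lambda_tau, lambda_S, theta):
    """Q = -2 lambda_tau lambda_S cos(2 theta) (eigenframe form)."""
    lt = np.asarray(lambda_tau, float)
    ls = np.asarray(lambda_S, float)
    th = np.asarray(theta, float)
    if np.any(lt < 0) or np.any(ls < 0):
        raise ValueError("eigenvalues must be nonnegative")
    return -2.0 * lt * ls * np.cos(2.0 * th)


def fold_axial_angle(delta) -> np.ndarray:
    """Fold a difference of axial angles into [0, pi/2]."""
    d = np.mod(np.asarray(delta, float), np.pi)
    return np.minimum(d, np.pi - d)


@dataclass
class GeometryField:
    """lambda_tau, lambda_S and their folded alignment angle theta per node."""

    grid: Grid2D
    times: np.ndarray
    lambda_tau: np.ndarray
    lambda_S: np.ndarray
    theta: np.ndarray  # [0, pi/2]; NaN where either eigenframe is degenerate
    attrs: dict = dc_field(default_factory=dict)

    def flux(self) -> np.ndarray:
        return flux_from_geometry(self.lambda_tau, self.lambda_S, self.theta)


def alignment_angle(tau: TensorField2D, S: TensorField2D) -> GeometryField:
    """Folded angle between the extensional eigenvectors of tau and S."""
    _check_meta(tau, S)
    ef_tau: EigenFrameField = eigenframe(tau)
    ef_S: EigenFrameField = eigenframe(S)
    theta = fold_axial_angle(ef_tau.angle - ef_S.angle)
    return GeometryField(grid=tau.grid, times=tau.times.copy(),
                         lambda_tau=ef_tau.lambda_max, lambda_S=ef_S.lambda_max,
                         theta=theta, attrs=dict(tau.attrs))


@dataclass
class FluxCurve:
    """Domain-averaged flux versus filter scale L."""

    L: np.ndarray
    mean: np.ndarray
    std: np.ndarray  # dispersion across frames
    n_frames: int
    quantity: str = "Qs"
    region: Optional[tuple] = None
    attrs: dict = dc_field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "L": self.L, "mean": self.mean, "std": self.std,
            "n_frames": self.n_frames, "quantity": self.quantity,
            "kernel": self.attrs.get("filter_kernel", ""),
            "padding": self.attrs.get("filter_padding", ""),
        })


def _region_mask(grid: Grid2D, region) -> np.ndarray:
    if region is None:
        return np.ones((grid.ny, grid.nx), dtype=bool)
    (xr0, xr1), (yr0, yr1) = region
    X, Y = grid.meshgrid()
    return (X >= xr0) & (X <= xr1) & (Y >= yr0) & (Y <= yr1)


def net_flux_curve(fld: VelocityField2D, L_list: Sequence[float],
                   spec_template: FilterSpec, region=None,
                   quantity: str = "Qs") -> FluxCurve:
    """Spatial mean of the flux over a region, then statistics across frames.

    For each L the flux map is averaged over the region intersected with
    the filter's interior margin; the curve reports the time mean and the
    standard deviation across frames.
    """
    L_arr = np.asarray(list(L_list), dtype=float)
    if L_arr.size == 0:
        raise ValueError("L_list is empty")
    if np.any(np.diff(L_arr) <= 0):
        raise ValueError("L_list must be strictly increasing")
    means = np.empty(L_arr.size)
    stds = np.empty(L_arr.size)
    reg = _region_mask(fld.grid, region)
    for i, L in enumerate(L_arr):
        spec = replace(spec_template, L=float(L))
        spec.validate_for_grid(fld.grid)
        low = lowpass(fld, spec)
        S = strain_rate(low)
        if quantity == "Qs":
            stress = sgs_reynolds_stress(fld, spec)
            qmap = sgs_flux_pointwise(stress, S)
        elif quantity == "Q":
            stress = turbulent_stress(fld, spec)
            qmap = flux_pointwise(stress, S)
        else:
            raise ValueError(f"unknown flux quantity {quantity!r}")
        valid = reg & interior_mask(fld.grid, spec)
        per_frame = []
        for k in range(fld.n_times):
            sel = valid & qmap.effective_mask()[k]
            if not sel.any():
                raise ValueError(f"averaging region empty at L = {L}")
            per_frame.append(float(np.mean(qmap.values[k][sel])))
        means[i] = np.mean(per_frame)
        stds[i] = np.std(per_frame, ddof=1) if len(per_frame) > 1 else 0.0
    return FluxCurve(L=L_arr, mean=means, std=stds, n_frames=fld.n_times,
                     quantity=quantity, region=region,
                     attrs=spec_template.meta())


DEFAULT_NEUTRAL_BAND = np.pi / 36.0  # 5 degrees


def classify_theta_s(swim_direction, shear_eigen_angle: float,
                     tolerance_band: float = DEFAULT_NEUTRAL_BAND) -> str:
    """Classify a swimming direction against the shear's extensional axis.

    theta_s is the folded angle between the swimming direction and the
    extensional eigenvector.  Returns ``aligned`` (theta_s < pi/4 - band),
    ``anti_aligned`` (theta_s > pi/4 + band) or ``neutral``.
    """
    d = np.asarray(swim_direction, float)
    norm = np.hypot(d[0], d[1])
    if norm == 0:
        raise ValueError("swim direction must be nonzero")
    ang = np.arctan2(d[1], d[0])
    theta_s = float(fold_axial_angle(ang - shear_eigen_angle))
    if theta_s < np.pi / 4 - tolerance_band:
        return "aligned"
    if theta_s > np.pi / 4 + tolerance_band:
        return "anti_aligned"
    return "neutral"


def effective_viscosity(Q: ScalarField2D, S: TensorField2D) -> ScalarField2D:
    """nu_e = Q / (2 S_ij S_ij): the eddy viscosity the flux implies.

    Negative values mark inverse flux (the sub-filter motions feed the
    resolved flow).  Nodes where S_ij S_ij is negligible are masked.
    """
    if not Q.grid.same_as(S.grid):
        raise ValueError("effective_viscosity: grid mismatch")
    s2 = _contract(S, S)
    scale = np.nanmean(np.where(S.effective_mask(), s2, np.nan))
    ok = s2 > 1e-14 * max(scale, np.finfo(float).tiny)
    nu = np.zeros_like(s2)
    np.divide(Q.values, 2.0 * s2, out=nu, where=ok)
    mask = ok & Q.effective_mask() & S.effective_mask()
    return ScalarField2D(grid=Q.grid, times=Q.times.copy(), values=nu,
                         mask=mask, attrs={**Q.attrs, "quantity": "nu_eff"})
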