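"""Spectral low-pass filtering at a cutoff scale L (the filter-space technique).

The filter suppresses velocity variations on scales smaller than L while
preserving the large-scale content.  Three kernels are provided, each
defined by its transfer function G(k):

* ``gaussian``       — G = exp(-k^2 sigma^2 / 2) with sigma^2 = L^2/12
                       (second moment matched to a top-hat of width L);
* ``sharp-spectral`` — isotropic cutoff, G = 1 for |k| <= pi/L, else 0;
* ``top-hat``        — separable box of width L, G = sinc(kx L/2) sinc(ky L/2).

Filtering is carried out by FFT on a padded copy of the frame; the padding
mode (``mirror``, ``periodic`` or ``zero``) controls the boundary
extension.  Because near-boundary filtering is contaminated by the
extension, spatial averages downstream exclude an interior margin
(default L/2).  Masked fields are filtered by normalized convolution:
the masked field and the mask are filtered separately and divided, and
nodes with mask coverage below 0.5 are masked in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .fields import Grid2D, ScalarField2D, VelocityField2D

__all__ = ["FilterSpec", "lowpass", "filtered_product", "residual",
           "filter_sweep", "interior_mask"]

_KERNEL_ALIASES = {
    "gaussian": "gaussian",
    "sharp": "sharp-spectral",
    "sharp-spectral": "sharp-spectral",
    "tophat": "top-hat",
    "top-hat": "top-hat",
}
_PADDINGS = ("mirror", "periodic", "zero")


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter settings: kernel, cutoff length L (cm), padding."""

    L: float
    kernel: str = "gaussian"
    padding: str = "mirror"
    interior_margin: Optional[float] = None  # cm; defaults to L/2

    def __post_init__(self) -> None:
        k = _KERNEL_ALIASES.get(self.kernel)
        if k is None:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        object.__setattr__(self, "kernel", k)
        if self.padding not in _PADDINGS:
            raise ValueError(f"unknown padding {self.padding!r}")
        if self.L <= 0:
            raise ValueError("cutoff length L must be positive")
        if self.interior_margin is not None and self.interior_margin < 0:
            raise ValueError("interior_margin must be nonnegative")

    @property
    def sigma(self) -> float:
        """Gaussian standard deviation implied by L (cm)."""
        return self.L / np.sqrt(12.0)

    @property
    def margin(self) -> float:
        return self.L / 2.0 if self.interior_margin is None else self.interior_margin

    def validate_for_grid(self, grid: Grid2D) -> None:
        if self.L <= 2.0 * max(grid.dx, grid.dy):
            raise ValueError(
                f"L = {self.L} must exceed twice the grid spacing "
                f"{max(grid.dx, grid.dy)}"
            )
        if self.L >= max(grid.extent_x, grid.extent_y):
            raise ValueError(f"L = {self.L} exceeds the domain extent")

    def meta(self) -> dict:
        return {"filter_kernel": self.kernel, "filter_L": self.L,
                "filter_padding": self.padding, "filter_margin": self.margin}


def _pad_widths(spec: FilterSpec, grid: Grid2D) -> tuple[int, int]:
    """Per-axis pad width in nodes (0 for periodic padding)."""
    if spec.padding == "periodic":
        return 0, 0
    if spec.kernel == "gaussian":
        reach = 8.0 * spec.sigma
    elif spec.kernel == "top-hat":
        reach = 0.6 * spec.L
    else:  # sharp-spectral: slowly decaying sinc kernel, generous pad
        reach = 3.0 * spec.L
    px = int(np.ceil(reach / grid.dx))
    py = int(np.ceil(reach / grid.dy))
    # np.pad 'reflect' cannot exceed the axis length minus one
    return min(px, grid.nx - 1), min(py, grid.ny - 1)


def _transfer(spec: FilterSpec, kx: np.ndarray, ky: np.ndarray) -> np.ndarray:
    KX, KY = np.meshgrid(kx, ky, indexing="xy")
    k2 = KX**2 + KY**2
    if spec.kernel == "gaussian":
        return np.exp(-0.5 * k2 * spec.sigma**2)
    if spec.kernel == "sharp-spectral":
        kc = np.pi / spec.L
        return (k2 <= kc**2 + 1e-30).astype(float)
    # top-hat: separable sinc; np.sinc(z) = sin(pi z)/(pi z)
    return np.sinc(KX * spec.L / (2.0 * np.pi)) * np.sinc(KY * spec.L / (2.0 * np.pi))


def _filter_frame(arr: np.ndarray, grid: Grid2D, spec: FilterSpec) -> np.ndarray:
    """Low-pass one (ny, nx) frame; returns the filtered frame."""
    px, py = _pad_widths(spec, grid)
    if spec.padding == "mirror" and (px or py):
        work = np.pad(arr, ((py, py), (px, px)), mode="reflect")
    elif spec.padding == "zero" and (px or py):
        work = np.pad(arr, ((py, py), (px, px)), mode="constant")
    else:
        work = arr
    ny, nx = work.shape
    kx = 2.0 * np.pi * np.fft.rfftfreq(nx, d=grid.dx)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=grid.dy)
    G = _transfer(spec, kx, ky)
    out = np.fft.irfft2(np.fft.rfft2(work) * G, s=work.shape)
    if px or py:
        out = out[py:py + grid.ny, px:px + grid.nx]
    return out


def _filter_masked(arr: np.ndarray, mask: np.ndarray, grid: Grid2D,
                   spec: FilterSpec) -> tuple[np.ndarray, np.ndarray]:
    """Normalized convolution of a masked frame; returns (values, out_mask)."""
    w = mask.astype(float)
    num = _filter_frame(np.where(mask, arr, 0.0), grid, spec)
    den = _filter_frame(w, grid, spec)
    ok = den >= 0.5
    out = np.full_like(num, np.nan)
    np.divide(num, den, out=out, where=ok)
    return out, ok


def lowpass(fld: VelocityField2D, spec: FilterSpec) -> VelocityField2D:
    """Return the filtered velocity field u^(L)."""
    spec.validate_for_grid(fld.grid)
    n = fld.n_times
    u = np.empty_like(fld.u)
    v = np.empty_like(fld.v)
    out_mask = None
    if fld.mask is None:
        for k in range(n):
            u[k] = _filter_frame(fld.u[k], fld.grid, spec)
            v[k] = _filter_frame(fld.v[k], fld.grid, spec)
    else:
        out_mask = np.empty_like(fld.mask)
        for k in range(n):
            u[k], mu = _filter_masked(fld.u[k], fld.mask[k], fld.grid, spec)
            v[k], mv = _filter_masked(fld.v[k], fld.mask[k], fld.grid, spec)
            out_mask[k] = mu & mv
    return VelocityField2D(grid=fld.grid, times=fld.times.copy(), u=u, v=v,
                           mask=out_mask, attrs={**fld.attrs, **spec.meta()})


def filtered_product(f: np.ndarray | ScalarField2D, g, *,
                     spec: FilterSpec, grid: Optional[Grid2D] = None,
                     times=None, mask=None) -> ScalarField2D:
    """Return (f*g)^(L): the pointwise product filtered at L.

    ``f`` and ``g`` may be ScalarField2D on the same grid or raw arrays
    accompanied by ``grid`` (and optionally ``times``/``mask``).
    """
    if isinstance(f, ScalarField2D):
        if not isinstance(g, ScalarField2D) or not g.grid.same_as(f.grid):
            raise ValueError("filtered_product: grid mismatch")
        grid, times = f.grid, f.times
        fa, ga = f.values, g.values
        if f.mask is not None or g.mask is not None:
            mask = f.effective_mask() & g.effective_mask()
    else:
        if grid is None:
            raise ValueError("filtered_product: grid required with raw arrays")
        fa = np.asarray(f, float)
        ga = np.asarray(g, float)
        if fa.ndim == 2:
            fa = fa[None]
        if ga.ndim == 2:
            ga = ga[None]
        if fa.shape != ga.shape:
            raise ValueError("filtered_product: shape mismatch")
        if times is None:
            times = np.arange(fa.shape[0], dtype=float)
    spec.validate_for_grid(grid)
    prod = fa * ga
    out = np.empty_like(prod)
    out_mask = None
    if mask is None:
        for k in range(prod.shape[0]):
            out[k] = _filter_frame(prod[k], grid, spec)
    else:
        out_mask = np.empty(prod.shape, dtype=bool)
        for k in range(prod.shape[0]):
            out[k], out_mask[k] = _filter_masked(prod[k], mask[k], grid, spec)
    return ScalarField2D(grid=grid, times=times, values=out, mask=out_mask,
                         attrs=spec.meta())


def residual(fld: VelocityField2D, spec: FilterSpec) -> VelocityField2D:
    """Return the sub-filter velocity u - u^(L)."""
    low = lowpass(fld, spec)
    mask = low.mask
    u = fld.u - low.u
    v = fld.v - low.v
    if mask is not None:
        u = np.where(mask, u, np.nan)
        v = np.where(mask, v, np.nan)
    return VelocityField2D(grid=fld.grid, times=fld.times.copy(), u=u, v=v,
                           mask=mask, attrs={**fld.attrs, **spec.meta()})


def filter_sweep(fld: VelocityField2D, L_list: Sequence[float],
                 spec_template: FilterSpec) -> list[VelocityField2D]:
    """Filter the field at each L in an increasing list, sharing kernel/padding."""
    L_arr = np.asarray(list(L_list), dtype=float)
    if L_arr.size == 0:
        return []
    if np.any(np.diff(L_arr) <= 0):
        raise ValueError("L_list must be strictly increasing")
    specs = [replace(spec_template, L=float(L)) for L in L_arr]
    for s in specs:
        s.validate_for_grid(fld.grid)
    return [lowpass(fld, s) for s in specs]


def interior_mask(grid: Grid2D, spec: FilterSpec) -> np.ndarray:
    """Boolean (ny, nx) mask of nodes at least ``spec.margin`` from every edge."""
    m = spec.margin
    X, Y = grid.meshgrid()
    return (
        (X >= grid.x0 + m) & (X <= grid.x0 + grid.extent_x - m)
        & (Y >= grid.y0 + m) & (Y <= grid.y0 + grid.extent_y - m)
    )
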