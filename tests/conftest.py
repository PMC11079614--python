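import numpy as np
import pytest

from shearflux import Grid2D, ShearSpec


@pytest.fixture
def lab_grid() -> Grid2D:
    """The 7 cm x 7 cm observation window at dx = 0.07 cm, centered."""
    return Grid2D(nx=101, ny=101, dx=0.07, dy=0.07, x0=-3.5, y0=-3.5)


@pytest.fixture
def small_grid() -> Grid2D:
    return Grid2D(nx=48, ny=48, dx=0.1, dy=0.1, x0=0.0, y0=0.0)


@pytest.fixture
def lab_shear() -> ShearSpec:
    """Linear shear ramping from -1.2 to +1.2 cm/s across 7 cm."""
    return ShearSpec(v_max=1.2, width=7.0)


def random_band_limited(grid: Grid2D, seed: int = 0, kmax_frac: float = 0.25,
                        amplitude: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Smooth periodic random (u, v) with content only below a wavenumber cap."""
    rng = np.random.default_rng(seed)
    kx = np.fft.rfftfreq(grid.nx, d=grid.dx)
    ky = np.fft.fftfreq(grid.ny, d=grid.dy)
    KX, KY = np.meshgrid(2 * np.pi * kx, 2 * np.pi * ky, indexing="xy")
    kcap = kmax_frac * np.pi / max(grid.dx, grid.dy)
    keep = (KX**2 + KY**2) <= kcap**2

    def gen():
        coeffs = (rng.standard_normal(KX.shape) + 1j * rng.standard_normal(KX.shape))
        coeffs = np.where(keep, coeffs, 0.0)
        coeffs[0, 0] = 0.0
        f = np.fft.irfft2(coeffs, s=(grid.ny, grid.nx))
        return amplitude * f / max(np.abs(f).max(), 1e-30)

    return gen(), gen()
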