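"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's FFT code paths: the Gaussian filter
oracle builds a sampled real-space kernel (with periodic images) and
convolves it by explicit summation; the tensor contraction oracle loops
over both index orders.
"""

import numpy as np


def direct_gaussian_filter(arr: np.ndarray, dx: float, dy: float,
                           sigma: float) -> np.ndarray:
    """Circular (periodic) convolution with a sampled Gaussian kernel.

    The kernel is sampled on the torus including +/-2 periodic images and
    normalized to unit sum; the convolution is an explicit double loop
    over output nodes.
    """
    ny, nx = arr.shape
    Lx, Ly = nx * dx, ny * dy
    x = dx * np.arange(nx)
    y = dy * np.arange(ny)
    X, Y = np.meshgrid(x, y, indexing="xy")
    kern = np.zeros_like(X)
    for mx in (-2, -1, 0, 1, 2):
        for my in (-2, -1, 0, 1, 2):
            kern += np.exp(-((X - mx * Lx) ** 2 + (Y - my * Ly) ** 2)
                           / (2.0 * sigma**2))
    kern /= kern.sum()
    out = np.empty_like(arr)
    for p in range(ny):
        for q in range(nx):
            shifted = np.roll(np.roll(kern, p, axis=0), q, axis=1)
            out[p, q] = np.sum(arr * shifted[::1, ::1])
    return out


def contraction_double_loop(tau_components, S_components) -> np.ndarray:
    """-sum_{i,j} tau_ij S_ij by looping over both index orders."""
    txx, txy, tyy = tau_components
    sxx, sxy, syy = S_components
    tau = {(0, 0): txx, (0, 1): txy, (1, 0): txy, (1, 1): tyy}
    S = {(0, 0): sxx, (0, 1): sxy, (1, 0): sxy, (1, 1): syy}
    total = np.zeros_like(np.asarray(txx, dtype=float))
    for i in (0, 1):
        for j in (0, 1):
            total = total + tau[(i, j)] * S[(i, j)]
    return -total
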