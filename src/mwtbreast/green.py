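"""Discretized 2D Helmholtz Green operator (method of moments, Richmond cells).

The domain integral operator

    (G v)(rho) = k_b^2 * Integral_Omega g(rho, rho') v(rho') drho',
    g(rho, rho') = (-j/4) H0^(2)(k_b |rho - rho'|),

is discretized by replacing each square cell with the circle of equal area
(radius ``a = pixel / sqrt(pi)``) over which the Green function integrates in
closed form:

    off-cell:  G_mn = (-j pi k a / 2) J1(k a) H0^(2)(k R_mn)
    self-cell: G_nn = (-j pi k a / 2) H1^(2)(k a) - 1

Because the coupling depends only on the cell-center offset, G is
block-Toeplitz with Toeplitz blocks; applying it is a 2D convolution with the
(2n-1) x (2n-1) offset kernel, evaluated with FFTs in O(n^2 log n).
"""

from __future__ import annotations

import numpy as np
from scipy.fft import fft2, ifft2, next_fast_len
from scipy.special import hankel2, jv

from .config import ImagingGrid, MeasurementConfig

__all__ = ["richmond_coupling", "richmond_self_term", "GreensOperator"]


def richmond_coupling(k: complex, a: float, r: np.ndarray) -> np.ndarray:
    """Off-cell coupling coefficient at center distance(s) ``r`` (> 0)."""
    return (-1j * np.pi * k * a / 2.0) * jv(1, k * a) * hankel2(0, k * r)


def richmond_self_term(k: complex, a: float) -> complex:
    """Self-cell coefficient (observation at the cell's own center)."""
    return complex((-1j * np.pi * k * a / 2.0) * hankel2(1, k * a) - 1.0)


class GreensOperator:
    """FFT-accelerated application of the discretized domain operator.

    Parameters
    ----------
    grid, config
        Imaging grid and measurement setup; the operator depends on the
        background wavenumber and the cell size only.
    """

    def __init__(self, grid: ImagingGrid, config: MeasurementConfig):
        self.grid = grid
        self.config = config
        self.k = config.wavenumber
        self.cell_radius = grid.pixel_size / np.sqrt(np.pi)

        n = grid.n
        d = grid.pixel_size
        off = np.arange(-(n - 1), n)
        DI, DJ = np.meshgrid(off, off, indexing="ij")
        R = d * np.hypot(DI, DJ)
        kernel = np.empty_like(R, dtype=complex)
        mask = R > 0
        kernel[mask] = richmond_coupling(self.k, self.cell_radius, R[mask])
        kernel[~mask] = richmond_self_term(self.k, self.cell_radius)
        self._kernel = kernel

        L = next_fast_len(2 * n - 1)
        self._L = L
        self._kernel_hat = fft2(kernel, s=(L, L))

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Return G v for a per-pixel complex field ``v`` (n x n or flat)."""
        n = self.grid.n
        flat_in = v.ndim == 1
        if v.size != n * n:
            raise ValueError(f"expected {n * n} entries, got {v.size}")
        V = np.asarray(v, dtype=complex).reshape(n, n)
        L = self._L
        out = ifft2(fft2(V, s=(L, L)) * self._kernel_hat)
        out = out[n - 1:2 * n - 1, n - 1:2 * n - 1]
        return out.ravel() if flat_in else out

    def dense(self) -> np.ndarray:
        """Full (n^2, n^2) matrix; for validation on small grids only."""
        n = self.grid.n
        if n > 32:
            raise ValueError("dense assembly is intended for small grids")
        idx = np.arange(n * n)
        ri, ci = np.divmod(idx, n)
        DI = ri[:, None] - ri[None, :]
        DJ = ci[:, None] - ci[None, :]
        return self._kernel[DI + (n - 1), DJ + (n - 1)]
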