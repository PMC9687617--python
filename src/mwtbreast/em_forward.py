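"""2D transverse-magnetic scattering: incident fields, state-equation solve,
scattered-field sampling, scattering-matrix assembly and the AWGN data model.

The coupled integral equations are

    E_s = A_e(eps', sigma, E_t) + n      (data equation, receivers on Gamma)
    E_t = E_i + A_i(eps', sigma, E_t)    (state equation, inside Omega)

with A_i the domain Green operator applied to chi * E_t (see ``green``), and
A_e the same radiation integral evaluated at the receiver positions.  The
state equation is solved iteratively (BiCGStab by default) with
FFT-accelerated operator applications.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.sparse.linalg import LinearOperator, bicgstab, lsqr
from scipy.special import hankel2, jv

from .config import ImagingGrid, MeasurementConfig
from .green import GreensOperator, richmond_coupling

__all__ = [
    "ScatteringMatrix",
    "ConvergenceError",
    "incident_field",
    "solve_total_field",
    "scattered_at_receivers",
    "assemble_scattering_matrix",
    "add_awgn",
]


class ConvergenceError(RuntimeError):
    """Iterative solve did not reach tolerance; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (relative residual {residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class ScatteringMatrix:
    """Multiview-multistatic scattered-field samples.

    ``values[v, r]`` is the scattered field recorded at receiver ``r`` while
    antenna ``v`` transmits.  With coincident transmitter/receiver positions
    and identical line sources the noiseless matrix is symmetric
    (reciprocity).
    """

    values: np.ndarray
    snr_db: float = np.inf
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("scattering matrix must be square")

    @property
    def n_antennas(self) -> int:
        return self.values.shape[0]


def incident_field(config: MeasurementConfig, grid: ImagingGrid,
                   view: int) -> np.ndarray:
    """Incident field of transmitting antenna ``view`` at all pixel centers.

    E_i(rho) = A * H0^(2)(k_b |rho - rho_src|); the source lies on Gamma,
    strictly outside the grid, so the field is finite at every pixel.
    """
    if not 0 <= view < config.n_antennas:
        raise IndexError(f"view {view} out of range [0, {config.n_antennas})")
    src = config.antenna_positions()[view]
    X, Y = grid.pixel_centers()
    R = np.hypot(X - src[0], Y - src[1])
    return config.source_amplitude * hankel2(0, config.wavenumber * R)


def solve_total_field(chi: np.ndarray, e_inc: np.ndarray,
                      op: GreensOperator, tol: float = 1e-6,
                      max_iter: int = 1000,
                      method: Literal["bicgstab", "cgnr"] = "bicgstab",
                      ) -> np.ndarray:
    """Solve the state equation (I - G X) E_t = E_i for the total field.

    Parameters
    ----------
    chi, e_inc
        Complex contrast and incident field on the operator's grid.
    tol
        Target relative residual ||E_t - E_i - G(chi E_t)|| / ||E_i||.
    method
        ``bicgstab`` (default) on the complex non-Hermitian system, or
        ``cgnr`` (LSQR-based normal-equations iteration) as a fallback.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = op.grid.n
    chi = np.asarray(chi, dtype=complex).reshape(n * n)
    b = np.asarray(e_inc, dtype=complex).reshape(n * n)
    if not np.any(chi):
        return b.reshape(n, n)

    def matvec(v: np.ndarray) -> np.ndarray:
        return v - op.apply(chi * v)

    A = LinearOperator((n * n, n * n), matvec=matvec, dtype=complex)
    if method == "bicgstab":
        x, info = bicgstab(A, b, rtol=tol, atol=0.0, maxiter=max_iter)
    elif method == "cgnr":
        res = lsqr(A, b, atol=tol, btol=tol, iter_lim=max_iter)
        x, info = res[0], 0
    else:
        raise ValueError(f"unknown method {method!r}")
    resid = np.linalg.norm(matvec(x) - b) / np.linalg.norm(b)
    if info != 0 or not np.isfinite(resid) or resid > 10 * tol:
        raise ConvergenceError("state-equation solve did not converge", resid)
    return x.reshape(n, n)


def _receiver_coupling(config: MeasurementConfig,
                       grid: ImagingGrid) -> np.ndarray:
    """(n_antennas, n_pixels) Richmond radiation coefficients to Gamma."""
    pos = config.antenna_positions()
    X, Y = grid.pixel_centers()
    R = np.hypot(pos[:, 0][:, None] - X.ravel()[None, :],
                 pos[:, 1][:, None] - Y.ravel()[None, :])
    a = grid.pixel_size / np.sqrt(np.pi)
    return richmond_coupling(config.wavenumber, a, R)


def scattered_at_receivers(chi: np.ndarray, e_tot: np.ndarray,
                           config: MeasurementConfig,
                           grid: ImagingGrid) -> np.ndarray:
    """Data equation: scattered field at every receiver on Gamma.

    E_s(r) = sum over cells of the Richmond radiation coefficient times the
    induced source chi * E_t.
    """
    w = (np.asarray(chi, dtype=complex).ravel()
         * np.asarray(e_tot, dtype=complex).ravel())
    if w.size != grid.n_pixels:
        raise ValueError("chi/e_tot size does not match the grid")
    return _receiver_coupling(config, grid) @ w


def assemble_scattering_matrix(chi: np.ndarray, config: MeasurementConfig,
                               grid: ImagingGrid, tol: float = 1e-6,
                               max_iter: int = 1000) -> ScatteringMatrix:
    """Full multiview-multistatic scattering matrix of a contrast map.

    For each transmitting view: incident field, state-equation solve, data
    equation at all receivers.  Raises ``ConvergenceError`` tagged with the
    failing view.
    """
    config.validate_against_grid(grid)
    op = GreensOperator(grid, config)
    coupling = _receiver_coupling(config, grid)
    chi_flat = np.asarray(chi, dtype=complex).ravel()
    S = np.empty((config.n_antennas, config.n_antennas), dtype=complex)
    for v in range(config.n_antennas):
        e_i = incident_field(config, grid, v)
        try:
            e_t = solve_total_field(chi, e_i, op, tol=tol, max_iter=max_iter)
        except ConvergenceError as exc:
            raise ConvergenceError(f"view {v}: {exc}", exc.residual) from exc
        S[v] = coupling @ (chi_flat * e_t.ravel())
    return ScatteringMatrix(values=S, snr_db=np.inf, noise_seed=None)


def add_awgn(s: ScatteringMatrix, snr_db: float,
             seed: int | None = None) -> ScatteringMatrix:
    """Add i.i.d. circular complex Gaussian noise at the requested SNR.

    The per-entry noise variance is ``mean(|S|^2) / 10^(snr_db / 10)``; real
    and imaginary parts each carry half of it.  ``snr_db = inf`` returns the
    input unchanged.
    """
    if np.isinf(snr_db):
        return s
    rng = np.random.default_rng(seed)
    S = s.values
    p_sig = float(np.mean(np.abs(S) ** 2))
    var = p_sig / 10.0 ** (snr_db / 10.0)
    noise = rng.normal(scale=np.sqrt(var / 2.0), size=S.shape + (2,))
    noisy = S + noise[..., 0] + 1j * noise[..., 1]
    return replace(s, values=noisy, snr_db=snr_db, noise_seed=seed)
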