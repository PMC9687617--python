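"""Analytic line-source scattering by a homogeneous circular cylinder.

Independent validation oracle for the method-of-moments solver: the exact
solution for a circular cylinder of complex relative permittivity eps_c in a
homogeneous background is a cylindrical-harmonic series.  With the
``exp(+j w t)`` convention and a unit line source at rho_s (outside the
cylinder, cylinder-centered polar coordinates), the addition theorem gives

    E_i = A sum_m J_m(k_b rho<) H_m^(2)(k_b rho>) e^{j m (phi - phi_s)}

and boundary matching of E_z and its radial derivative at rho = a yields the
scattering (a_m) and interior (b_m) coefficients.  The series truncation
order is chosen adaptively.
"""

from __future__ import annotations

import numpy as np
from scipy.special import hankel2, jv

from .config import C0, MeasurementConfig

__all__ = [
    "cylinder_coefficients",
    "mie_fields",
    "mie_scattering_matrix",
    "optical_theorem_residual",
]

_MAX_ORDER = 400


def _jvp(m: np.ndarray, z: complex) -> np.ndarray:
    return 0.5 * (jv(m - 1, z) - jv(m + 1, z))


def _h2vp(m: np.ndarray, z: complex) -> np.ndarray:
    return 0.5 * (hankel2(m - 1, z) - hankel2(m + 1, z))


def cylinder_coefficients(m_max: int, k_b: complex, k_c: complex,
                          radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Scattering and interior coefficients (a_m, b_m) for m = 0..m_max.

    Continuity of E_z and dE_z/drho at rho = radius:

        J_m(kb a) + a_m H_m^(2)(kb a) = b_m J_m(kc a)
        kb J'_m(kb a) + a_m kb H'_m(kb a) = b_m kc J'_m(kc a)
    """
    m = np.arange(m_max + 1)
    zb, zc = k_b * radius, k_c * radius
    Jb, Jc = jv(m, zb), jv(m, zc)
    Hb = hankel2(m, zb)
    Jbp, Jcp = _jvp(m, zb), _jvp(m, zc)
    Hbp = _h2vp(m, zb)
    den = k_c * Jcp * Hb - k_b * Hbp * Jc
    a_m = (k_b * Jbp * Jc - k_c * Jcp * Jb) / den
    # numerator is the Wronskian -k_b (Jb Hbp - Jbp Hb) = 2j / (pi * radius)
    b_m = k_b * (Jbp * Hb - Jb * Hbp) / den
    return a_m, b_m


def _series(cyl_radius: float, center: np.ndarray, k_b: complex,
            k_c: complex, source: np.ndarray, amplitude: complex,
            points: np.ndarray, part: str, m_max: int) -> np.ndarray:
    rel_s = source - center
    rho_s = np.hypot(*rel_s)
    phi_s = np.arctan2(rel_s[1], rel_s[0])
    rel = points - center
    rho = np.hypot(rel[:, 0], rel[:, 1])
    phi = np.arctan2(rel[:, 1], rel[:, 0])

    a_m, b_m = cylinder_coefficients(m_max, k_b, k_c, cyl_radius)
    m = np.arange(m_max + 1)
    # e^{jm dphi} + e^{-jm dphi} = 2 cos(m dphi); m=0 counted once
    weight = np.where(m == 0, 1.0, 2.0)
    Hs = hankel2(m, k_b * rho_s)

    out = np.zeros(len(points), dtype=complex)
    inside = rho <= cyl_radius
    cosm = np.cos(np.outer(phi - phi_s, m))

    ext = ~inside
    if np.any(ext):
        Hm = hankel2(m[None, :], k_b * rho[ext, None])
        out[ext] = (weight[None, :] * a_m[None, :] * Hs[None, :]
                    * Hm * cosm[ext]).sum(axis=1)
        if part == "total":
            R = np.hypot(points[ext, 0] - source[0],
                         points[ext, 1] - source[1])
            out[ext] += hankel2(0, k_b * R)
    if np.any(inside):
        Jm = jv(m[None, :], k_c * rho[inside, None])
        tot = (weight[None, :] * b_m[None, :] * Hs[None, :]
               * Jm * cosm[inside]).sum(axis=1)
        if part == "total":
            out[inside] = tot
        else:
            R = np.hypot(points[inside, 0] - source[0],
                         points[inside, 1] - source[1])
            out[inside] = tot - hankel2(0, k_b * R)
    return amplitude * out


def mie_fields(cyl_radius: float, cyl_center, cyl_rel_permittivity: complex,
               config: MeasurementConfig, view: int, eval_points,
               part: str = "scattered", rel_tol: float = 1e-10) -> np.ndarray:
    """Exact field of the cylinder problem at arbitrary evaluation points.

    Parameters
    ----------
    part
        ``"scattered"`` or ``"total"``; inside the cylinder the scattered
        part is defined as total minus incident.
    rel_tol
        Adaptive truncation: the order is increased in steps of 5 until the
        result changes by less than ``rel_tol`` in relative 2-norm.
    """
    if part not in ("scattered", "total"):
        raise ValueError("part must be 'scattered' or 'total'")
    center = np.asarray(cyl_center, dtype=float)
    points = np.atleast_2d(np.asarray(eval_points, dtype=float))
    k_b = config.wavenumber
    if np.imag(complex(cyl_rel_permittivity)) > 0:
        raise ValueError("Im(eps_c) > 0 is active under exp(+jwt)")
    k_c = config.omega / C0 * np.sqrt(complex(cyl_rel_permittivity))
    source = config.antenna_positions()[view]
    if np.hypot(*(source - center)) <= cyl_radius:
        raise ValueError("source must lie outside the cylinder")

    m_max = int(np.ceil(abs(k_c) * cyl_radius + abs(k_b) * cyl_radius)) + 10
    prev = _series(cyl_radius, center, k_b, k_c, source,
                   config.source_amplitude, points, part, m_max)
    while True:
        m_max += 5
        if m_max > _MAX_ORDER:
            raise RuntimeError("cylindrical-harmonic series did not converge")
        cur = _series(cyl_radius, center, k_b, k_c, source,
                      config.source_amplitude, points, part, m_max)
        scale = np.linalg.norm(cur)
        if scale == 0 or np.linalg.norm(cur - prev) <= rel_tol * scale:
            return cur
        prev = cur


def mie_scattering_matrix(cyl_radius: float, cyl_center,
                          cyl_rel_permittivity: complex,
                          config: MeasurementConfig) -> np.ndarray:
    """Exact multiview-multistatic scattering matrix of the cylinder."""
    pos = config.antenna_positions()
    S = np.empty((config.n_antennas, config.n_antennas), dtype=complex)
    for v in range(config.n_antennas):
        S[v] = mie_fields(cyl_radius, cyl_center, cyl_rel_permittivity,
                          config, v, pos, part="scattered")
    return S


def optical_theorem_residual(cyl_radius: float,
                             cyl_rel_permittivity: complex,
                             config: MeasurementConfig,
                             m_max: int = 80) -> float:
    """Coefficient-level optical theorem for a lossless cylinder.

    For a lossless scatterer the modal S-matrix entries 1 + 2 a_m are
    unimodular, i.e. |a_m|^2 = -Re(a_m) for every m; the returned residual
    |sum(|a_m|^2 + Re a_m)| / sum |a_m|^2 vanishes when energy is conserved.
    """
    k_b = config.wavenumber
    k_c = config.omega / C0 * np.sqrt(complex(cyl_rel_permittivity))
    a_m, _ = cylinder_coefficients(m_max, k_b, k_c, cyl_radius)
    w = np.where(np.arange(m_max + 1) == 0, 1.0, 2.0)
    total = float(np.sum(w * np.abs(a_m) ** 2))
    resid = float(abs(np.sum(w * (np.abs(a_m) ** 2 + a_m.real))))
    return resid / total
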