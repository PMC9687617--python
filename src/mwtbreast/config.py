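"""Measurement geometry and imaging-grid definitions.

The imaging problem is posed on a square domain Omega discretized into n x n
square pixels, surrounded by a circle Gamma of antennas acting in a
multiview-multistatic fashion: each antenna transmits in turn while all
antennas record the scattered field.

Conventions (fixed package-wide):

* physical coordinates in meters, origin at the domain center, x rightward,
  y upward;
* pixel (0, 0) sits at the (-x, -y) corner; arrays are indexed
  ``[row, col]`` with ``row`` along y and ``col`` along x; flattening is
  row-major;
* time convention ``exp(+j w t)``, so the relative complex permittivity is
  ``eps_r = eps' - j sigma / (w eps0)`` and outgoing waves carry the Hankel
  function of the second kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m
MU0 = 4e-7 * np.pi       # vacuum permeability, H/m
C0 = 1.0 / np.sqrt(EPS0 * MU0)


@dataclass(frozen=True)
class MeasurementConfig:
    """Antenna ring and background medium of the tomographic system.

    Parameters
    ----------
    n_antennas
        Number of z-oriented line sources, equally spaced on the circle
        Gamma.  Antenna ``k`` sits at angle ``2 pi k / n_antennas``.
    radius
        Radius of Gamma in meters.  Must keep all antennas outside the
        imaging domain.
    frequency
        Operating frequency in Hz (single-frequency system).
    background_rel_permittivity
        Complex relative permittivity ``eps_b`` of the homogeneous coupling
        medium.  Under the ``exp(+j w t)`` convention a passive medium has
        ``Im(eps_b) <= 0``.
    source_amplitude
        Complex scale of the line source; the incident field is
        ``A * H0^(2)(k_b |rho - rho_src|)``.  Absolute scale is immaterial
        to the inverter (inputs are normalized) but must be consistent
        between dataset generation and inversion.
    """

    n_antennas: int = 30
    radius: float = 0.12
    frequency: float = 1e9
    background_rel_permittivity: complex = 20.0 - 0.0j
    source_amplitude: complex = 1.0 + 0.0j

    def __post_init__(self) -> None:
        if self.n_antennas < 3:
            raise ValueError("need at least 3 antennas")
        if self.radius <= 0 or self.frequency <= 0:
            raise ValueError("radius and frequency must be positive")
        if np.imag(self.background_rel_permittivity) > 0:
            raise ValueError(
                "Im(eps_b) > 0 is an active medium under the exp(+jwt) "
                "convention"
            )

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency

    @property
    def wavenumber(self) -> complex:
        """Background wavenumber k_b = (w / c) sqrt(eps_b).

        The principal square root of ``eps' - j eps''`` has Re > 0 and
        Im <= 0, which gives decay of the outgoing H0^(2) wave in a lossy
        medium.
        """
        return complex(self.omega / C0 * np.sqrt(
            complex(self.background_rel_permittivity)))

    def antenna_positions(self) -> np.ndarray:
        """(n_antennas, 2) array of antenna (x, y) coordinates on Gamma."""
        k = np.arange(self.n_antennas)
        theta = 2.0 * np.pi * k / self.n_antennas
        return self.radius * np.column_stack([np.cos(theta), np.sin(theta)])

    def validate_against_grid(self, grid: "ImagingGrid") -> None:
        half_diag = grid.side * np.sqrt(2.0) / 2.0
        if self.radius <= half_diag:
            raise ValueError(
                f"measurement radius {self.radius} m must exceed half the "
                f"grid diagonal {half_diag:.4f} m (antennas outside Omega)"
            )


@dataclass(frozen=True)
class ImagingGrid:
    """Square imaging domain of side ``side`` meters, n x n pixels."""

    side: float = 0.15
    n: int = 108

    def __post_init__(self) -> None:
        if self.side <= 0 or self.n < 2:
            raise ValueError("invalid grid")

    @property
    def pixel_size(self) -> float:
        return self.side / self.n

    @property
    def n_pixels(self) -> int:
        return self.n * self.n

    def axis_coords(self) -> np.ndarray:
        """Cell-center coordinates along one axis, symmetric about 0."""
        d = self.pixel_size
        return -self.side / 2.0 + d * (np.arange(self.n) + 0.5)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) meshgrids of cell centers, shape (n, n), row along y."""
        c = self.axis_coords()
        X, Y = np.meshgrid(c, c, indexing="xy")
        return X, Y


def complex_permittivity(eps_prime: np.ndarray, sigma: np.ndarray,
                         omega: float) -> np.ndarray:
    """eps_r = eps' - j sigma / (w eps0)."""
    return np.asarray(eps_prime) - 1j * np.asarray(sigma) / (omega * EPS0)


def contrast(eps_prime: np.ndarray, sigma: np.ndarray,
             config: MeasurementConfig) -> np.ndarray:
    """Complex contrast chi = (eps_r - eps_b) / eps_b on the grid."""
    eps_r = complex_permittivity(eps_prime, sigma, config.omega)
    eps_b = complex(config.background_rel_permittivity)
    return (eps_r - eps_b) / eps_b
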