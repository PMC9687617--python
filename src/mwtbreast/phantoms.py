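"""Stochastic generator of realistic 2D numerical breast phantoms.

Each phantom is an elliptical breast cross-section with a thin skin layer,
an interior segmented into adipose, transitional and fibroglandular tissue
driven by a scale-invariant (multifractal-like) random field, and per-pixel
dielectric properties (relative permittivity eps', conductivity sigma) drawn
from tissue-specific truncated normal distributions, smoothed within each
tissue to emulate the spatial correlation of real tissue maps.

Four density classes A-D (from mostly-adipose to mostly-fibroglandular)
control the tissue composition ranges:

    class  fibroglandular  transitional  adipose   (% of interior)
      A        5-20            5-15       65-90
      B       20-30           10-20       50-70
      C       30-40           15-20       40-55
      D       40-65           20-25       10-40

Drawn percentage triples are renormalized to sum to 100.  All randomness
flows through a single seed, so generation is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

from .config import EPS0, ImagingGrid, MeasurementConfig

__all__ = [
    "CLASS_FRACTION_TABLE",
    "GeneratorConfig",
    "Geometry",
    "BreastPhantom",
    "sample_geometry",
    "multifractal_field",
    "segment_tissues",
    "assign_dielectrics",
    "apply_spatial_correlation",
    "generate_phantom",
    "measure_skin_thickness",
]

# tissue labels
BACKGROUND, SKIN, ADIPOSE, TRANSITIONAL, FIBROGLANDULAR = 0, 1, 2, 3, 4

# per-class (fibroglandular, transitional, adipose) percentage ranges
CLASS_FRACTION_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "A": {"fibroglandular": (5, 20), "transitional": (5, 15),
          "adipose": (65, 90)},
    "B": {"fibroglandular": (20, 30), "transitional": (10, 20),
          "adipose": (50, 70)},
    "C": {"fibroglandular": (30, 40), "transitional": (15, 20),
          "adipose": (40, 55)},
    "D": {"fibroglandular": (40, 65), "transitional": (20, 25),
          "adipose": (10, 40)},
}

# per-tissue (mean, std) of eps' and sigma [S/m] at 1 GHz; truncated to
# eps' >= 1, sigma >= 0.  Values consistent with published large-scale
# measurements of breast-tissue dielectric properties.
DEFAULT_TISSUE_STATS: dict[int, dict[str, tuple[float, float]]] = {
    SKIN: {"eps": (40.0, 3.0), "sigma": (0.90, 0.10)},
    ADIPOSE: {"eps": (5.5, 1.0), "sigma": (0.08, 0.03)},
    TRANSITIONAL: {"eps": (28.0, 5.0), "sigma": (0.45, 0.10)},
    FIBROGLANDULAR: {"eps": (49.0, 6.0), "sigma": (0.90, 0.15)},
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable parameters of the phantom generator (meters / radians)."""

    axis_range: tuple[float, float] = (0.065, 0.12)
    center_jitter_radius: float = 0.01
    orientation_range: tuple[float, float] = (0.0, 2.0 * np.pi)
    skin_thickness_range: tuple[float, float] = (0.0015, 0.0025)
    spectral_exponent: float = 3.0      # power-law slope of the field PSD
    cascade_intensity: float = 1.0      # log-normal pointwise exponentiation
    correlation_length: float = 2.0     # within-tissue smoothing, pixels
    tissue_stats: dict = field(default_factory=lambda: DEFAULT_TISSUE_STATS)
    class_fraction_table: dict = field(
        default_factory=lambda: CLASS_FRACTION_TABLE)

    def __post_init__(self) -> None:
        for lo, hi in (self.axis_range, self.skin_thickness_range):
            if not lo < hi:
                raise ValueError("degenerate range")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be >= 0")
        for cls, row in self.class_fraction_table.items():
            lo = sum(r[0] for r in row.values())
            hi = sum(r[1] for r in row.values())
            if not lo <= 100 <= hi:
                raise ValueError(f"class {cls} ranges cannot sum to 100")


@dataclass(frozen=True)
class Geometry:
    """Sampled breast geometry: full axis lengths, center, tilt, skin."""

    axis_a: float
    axis_b: float
    center: tuple[float, float]
    orientation: float
    skin_thickness: float


@dataclass(frozen=True)
class BreastPhantom:
    """Tissue labels plus dielectric maps on the imaging grid."""

    tissue_map: np.ndarray     # int8 labels, (n, n)
    eps_map: np.ndarray        # relative permittivity eps'
    sigma_map: np.ndarray      # conductivity, S/m
    geometry: Geometry
    breast_class: str
    seed: int


def sample_geometry(cfg: GeneratorConfig, rng: np.random.Generator,
                    grid: ImagingGrid | None = None,
                    max_attempts: int = 100) -> Geometry:
    """Draw ellipse axes, center, orientation and skin thickness.

    Axis lengths (full diameters) are uniform in ``axis_range``, the center
    uniform in a disc, orientation uniform on the circle, skin thickness
    uniform in its range.  If a grid is given, resample until the ellipse
    (skin included) fits inside the domain.
    """
    for _ in range(max_attempts):
        a, b = rng.uniform(*cfg.axis_range, size=2)
        r = cfg.center_jitter_radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        center = (r * np.cos(phi), r * np.sin(phi))
        orientation = rng.uniform(*cfg.orientation_range)
        t = rng.uniform(*cfg.skin_thickness_range)
        geom = Geometry(a, b, center, orientation, t)
        if grid is None:
            return geom
        reach = max(a, b) / 2.0
        half = grid.side / 2.0
        if (abs(center[0]) + reach <= half) and (abs(center[1]) + reach <= half):
            return geom
    raise RuntimeError("could not fit breast geometry inside the domain")


def multifractal_field(grid: ImagingGrid, rng: np.random.Generator,
                       spectral_exponent: float = 3.0,
                       cascade_intensity: float = 1.0) -> np.ndarray:
    """Scale-invariant random field, standardized to zero mean, unit std.

    Spectral synthesis: white Gaussian Fourier coefficients shaped by an
    isotropic power-law spectrum |f|^(-beta/2) in amplitude, followed by
    pointwise exponentiation (log-normal cascade surrogate) to introduce
    the heavy-tailed, intermittent structure of multiplicative cascades.
    """
    n = grid.n
    f = np.fft.fftfreq(n)
    FX, FY = np.meshgrid(f, f, indexing="ij")
    rho = np.hypot(FX, FY)
    rho[0, 0] = np.inf  # kill DC
    amp = rho ** (-spectral_exponent / 2.0)
    phase = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    g = np.fft.ifft2(amp * phase).real
    g = (g - g.mean()) / g.std()
    if cascade_intensity != 0.0:
        g = np.exp(cascade_intensity * g)
    return (g - g.mean()) / g.std()


def _ellipse_mask(grid: ImagingGrid, geom: Geometry,
                  shrink: float = 0.0) -> np.ndarray:
    """Pixels whose centers fall inside the ellipse shrunk by ``shrink`` m
    (uniform inward offset of both semi-axes)."""
    X, Y = grid.pixel_centers()
    dx, dy = X - geom.center[0], Y - geom.center[1]
    c, s = np.cos(geom.orientation), np.sin(geom.orientation)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    sa = geom.axis_a / 2.0 - shrink
    sb = geom.axis_b / 2.0 - shrink
    if sa <= 0 or sb <= 0:
        return np.zeros((grid.n, grid.n), dtype=bool)
    return (u / sa) ** 2 + (v / sb) ** 2 <= 1.0


def segment_tissues(field_map: np.ndarray, geom: Geometry,
                    target_class: str, cfg: GeneratorConfig,
                    rng: np.random.Generator,
                    grid: ImagingGrid) -> tuple[np.ndarray, dict]:
    """Threshold the interior random field into the three tissue types.

    Target percentages are drawn uniformly within the class ranges and
    renormalized to 100; the interior field is cut at its empirical
    quantiles so achieved pixel fractions match the targets to quantile
    rounding.  Highest field values become fibroglandular, lowest adipose.
    The skin is the annulus between the full ellipse and the ellipse eroded
    by the sampled thickness, closed with a one-pixel boundary layer so it
    never breaks on coarse grids.
    """
    if target_class not in cfg.class_fraction_table:
        raise ValueError(f"unknown breast class {target_class!r}")
    outer = _ellipse_mask(grid, geom)
    inner = _ellipse_mask(grid, geom, shrink=geom.skin_thickness)
    boundary = outer & ~binary_erosion(outer)
    skin = (outer & ~inner) | boundary
    interior = outer & ~skin
    n_int = int(interior.sum())
    if n_int < 100:
        raise RuntimeError(
            f"breast interior too small ({n_int} pixels) on this grid")

    # Draw fibroglandular and transitional percentages uniformly in their
    # class ranges; adipose takes the remainder to 100, which the table's
    # construction keeps inside the adipose range for every class.
    row = cfg.class_fraction_table[target_class]
    targets = {
        "fibroglandular": rng.uniform(*row["fibroglandular"]),
        "transitional": rng.uniform(*row["transitional"]),
    }
    targets["adipose"] = 100.0 - sum(targets.values())
    lo, hi = row["adipose"]
    if not lo <= targets["adipose"] <= hi:
        targets["adipose"] = float(np.clip(targets["adipose"], lo, hi))
        scale = (100.0 - targets["adipose"]) / (
            targets["fibroglandular"] + targets["transitional"])
        targets["fibroglandular"] *= scale
        targets["transitional"] *= scale

    vals = np.asarray(field_map)[interior]
    q_adip = np.quantile(vals, targets["adipose"] / 100.0)
    q_trans = np.quantile(
        vals, (targets["adipose"] + targets["transitional"]) / 100.0)

    labels = np.zeros((grid.n, grid.n), dtype=np.int8)
    labels[skin] = SKIN
    fm = np.asarray(field_map)
    labels[interior & (fm <= q_adip)] = ADIPOSE
    labels[interior & (fm > q_adip) & (fm <= q_trans)] = TRANSITIONAL
    labels[interior & (fm > q_trans)] = FIBROGLANDULAR
    return labels, targets


def _truncated_normal(rng: np.random.Generator, mean: float, std: float,
                      lower: float, size: int) -> np.ndarray:
    """Resampling-based truncated normal draw (lower bound only)."""
    out = rng.normal(mean, std, size)
    bad = out < lower
    while np.any(bad):
        out[bad] = rng.normal(mean, std, int(bad.sum()))
        bad = out < lower
    return out


def assign_dielectrics(tissue_map: np.ndarray, cfg: GeneratorConfig,
                       rng: np.random.Generator,
                       config: MeasurementConfig,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel eps' and sigma from tissue-specific truncated normals.

    Background pixels take the coupling-medium values (eps' = Re(eps_b),
    sigma from Im(eps_b) via sigma = -Im(eps_b) * w * eps0).
    """
    eps_b = complex(config.background_rel_permittivity)
    eps = np.full(tissue_map.shape, eps_b.real, dtype=float)
    sigma = np.full(tissue_map.shape, -eps_b.imag * config.omega * EPS0,
                    dtype=float)
    for label, stats in cfg.tissue_stats.items():
        mask = tissue_map == label
        k = int(mask.sum())
        if k == 0:
            continue
        m_e, s_e = stats["eps"]
        m_s, s_s = stats["sigma"]
        eps[mask] = _truncated_normal(rng, m_e, s_e, 1.0, k)
        sigma[mask] = _truncated_normal(rng, m_s, s_s, 0.0, k)
    return eps, sigma


def apply_spatial_correlation(eps: np.ndarray, sigma: np.ndarray,
                              tissue_map: np.ndarray,
                              correlation_length: float,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Within-tissue Gaussian smoothing of the dielectric maps.

    Filtering is masked per tissue region (normalized convolution), so
    values never bleed across tissue boundaries and the label map is
    untouched.  ``correlation_length = 0`` is the identity.
    """
    if correlation_length == 0:
        return eps.copy(), sigma.copy()
    out_e, out_s = eps.copy(), sigma.copy()
    for label in np.unique(tissue_map):
        if label == BACKGROUND:
            continue
        mask = (tissue_map == label).astype(float)
        norm = gaussian_filter(mask, correlation_length)
        m = mask > 0
        for src, dst in ((eps, out_e), (sigma, out_s)):
            sm = gaussian_filter(src * mask, correlation_length)
            dst[m] = sm[m] / norm[m]
    return out_e, out_s


def generate_phantom(cfg: GeneratorConfig, target_class: str,
                     grid: ImagingGrid, seed: int,
                     config: MeasurementConfig | None = None,
                     ) -> BreastPhantom:
    """Full phantom generation pipeline, deterministic given the seed."""
    if config is None:
        config = MeasurementConfig()
    rng = np.random.default_rng(seed)
    geom = sample_geometry(cfg, rng, grid)
    fm = multifractal_field(grid, rng, cfg.spectral_exponent,
                            cfg.cascade_intensity)
    labels, _ = segment_tissues(fm, geom, target_class, cfg, rng, grid)
    eps, sigma = assign_dielectrics(labels, cfg, rng, config)
    eps, sigma = apply_spatial_correlation(eps, sigma, labels,
                                           cfg.correlation_length)
    return BreastPhantom(tissue_map=labels, eps_map=eps, sigma_map=sigma,
                         geometry=geom, breast_class=target_class, seed=seed)


def measure_skin_thickness(phantom: BreastPhantom,
                           grid: ImagingGrid) -> float:
    """Estimate the skin-layer thickness from the label map, in meters.

    Thickness = skin area / ellipse perimeter (Ramanujan approximation),
    the raster analogue of averaging normal-direction crossings.
    """
    geom = phantom.geometry
    area = float((phantom.tissue_map == SKIN).sum()) * grid.pixel_size ** 2
    a, b = geom.axis_a / 2.0, geom.axis_b / 2.0
    h = ((a - b) / (a + b)) ** 2
    perimeter = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
    return area / perimeter


def phantom_contrast(phantom: BreastPhantom,
                     config: MeasurementConfig) -> np.ndarray:
    """Complex contrast map of a phantom; exactly zero outside the breast."""
    from .config import contrast as _contrast

    chi = _contrast(phantom.eps_map, phantom.sigma_map, config)
    chi[phantom.tissue_map == BACKGROUND] = 0.0
    return chi
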