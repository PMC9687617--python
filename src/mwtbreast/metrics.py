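"""Reconstruction quality metrics.

Per-map measures: SSIM (Gaussian-windowed structural similarity), NRMSE
(error energy over reference energy) and CORR (Pearson correlation in
amplitude).  Population-level spectral indicator: the mean 2D power
spectrum of the retrieved complex-permittivity maps,

    T(nu, theta) = (1/N) sum_n |F(x_n)|^2,

averaged over the angular coordinate into a one-dimensional radial
spectrum

    S(nu) = (1 / 2 pi) Integral T(nu, theta) dtheta,

which quantifies how much spatial-frequency content an inverter preserves
(band-limited inverters act as low-pass filters on the true profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import MeasurementConfig, complex_permittivity
from .dataset import Dataset, devectorize_output

__all__ = [
    "ssim",
    "nrmse",
    "corr",
    "mean_power_spectrum",
    "radial_spectrum",
    "RadialSpectrum",
    "MetricsReport",
    "evaluate_testset",
    "baseline_predictor",
]


def ssim(est: np.ndarray, ref: np.ndarray, data_range: float | None = None,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Structural similarity with an 11x11 Gaussian window (sigma 1.5).

    Local means/variances/covariance are Gaussian-weighted (reflect
    padding, truncated at 3.5 sigma, i.e. an 11-tap kernel), the SSIM map
    is edge-cropped by the window half-width, and the dynamic range
    defaults to ``max(ref) - min(ref)``.
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        data_range = float(ref.max() - ref.min())
        if data_range == 0:
            raise ValueError("constant reference map: pass data_range "
                             "explicitly")
    trunc = 3.5
    f = lambda a: gaussian_filter(a, sigma, mode="reflect", truncate=trunc)
    mu_x, mu_y = f(est), f(ref)
    sxx = f(est * est) - mu_x ** 2
    syy = f(ref * ref) - mu_y ** 2
    sxy = f(est * ref) - mu_x * mu_y
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    num = (2 * mu_x * mu_y + c1) * (2 * sxy + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (sxx + syy + c2)
    s = num / den
    pad = int(trunc * sigma + 0.5)
    return float(s[pad:-pad, pad:-pad].mean())


def nrmse(est: np.ndarray, ref: np.ndarray) -> float:
    """||est - ref||_2 / ||ref||_2 (0 = perfect, 1 = zero estimate)."""
    ref = np.asarray(ref, dtype=float)
    denom = np.linalg.norm(ref)
    if denom == 0:
        raise ValueError("reference map is identically zero")
    return float(np.linalg.norm(np.asarray(est, dtype=float) - ref) / denom)


def corr(est: np.ndarray, ref: np.ndarray) -> float:
    """Pearson correlation of the flattened maps, reported in amplitude."""
    x = np.asarray(est, dtype=float).ravel()
    y = np.asarray(ref, dtype=float).ravel()
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant map")
    return float(abs(np.corrcoef(x, y)[0, 1]))


def mean_power_spectrum(maps: list[np.ndarray]) -> np.ndarray:
    """Mean squared magnitude of the centered 2D DFT over the profiles."""
    if len(maps) == 0:
        raise ValueError("empty profile list")
    shape = np.shape(maps[0])
    T = np.zeros(shape, dtype=float)
    for x in maps:
        if np.shape(x) != shape:
            raise ValueError("profiles must share one shape")
        T += np.abs(np.fft.fftshift(np.fft.fft2(x))) ** 2
    return T / len(maps)


@dataclass(frozen=True)
class RadialSpectrum:
    """Angle-averaged power spectrum on annular frequency bins."""

    nu: np.ndarray          # bin centers, cycles per meter
    values: np.ndarray      # S(nu) >= 0
    n_profiles: int
    component: str = "complex permittivity"


def radial_spectrum(T: np.ndarray, side: float = 0.15,
                    n_profiles: int = 1) -> RadialSpectrum:
    """Angular average of ``T`` by annular binning, one frequency sample wide.

    Each Cartesian bin is assigned to the annulus whose index is its radial
    frequency rounded to the nearest sample; S(nu_k) is the mean of T over
    annulus k.  Bin centers are k / side in cycles per meter.
    """
    n = T.shape[0]
    f = np.fft.fftshift(np.fft.fftfreq(n)) * n  # integer frequency samples
    FX, FY = np.meshgrid(f, f, indexing="ij")
    r = np.rint(np.hypot(FX, FY)).astype(int)
    kmax = n // 2
    values = np.array([T[r == k].mean() for k in range(kmax + 1)])
    nu = np.arange(kmax + 1) / side
    return RadialSpectrum(nu=nu, values=values, n_profiles=n_profiles)


@dataclass
class MetricsReport:
    """Per-sample metric table plus per-class and overall aggregates.

    ``per_sample[metric][channel]`` is a vector over test samples, with
    channel ``"eps"`` or ``"sigma"``; aggregates map class label ->
    (mean, std).
    """

    per_sample: dict
    class_labels: np.ndarray
    aggregates: dict = field(default_factory=dict)

    def aggregate(self) -> dict:
        classes = np.unique(self.class_labels)
        agg: dict = {}
        for metric, chans in self.per_sample.items():
            agg[metric] = {}
            for chan, vals in chans.items():
                rows = {
                    "overall": (float(np.mean(vals)), float(np.std(vals)))}
                for c in classes:
                    sel = vals[self.class_labels == c]
                    rows[str(c)] = (float(np.mean(sel)), float(np.std(sel)))
                agg[metric][chan] = rows
        self.aggregates = agg
        return agg


def baseline_predictor(ds: Dataset) -> np.ndarray:
    """Constant predictor: the mean training-target image (one vector)."""
    return ds.targets[ds.train_idx].astype(float).mean(axis=0)


def evaluate_testset(model, ds: Dataset,
                     config: MeasurementConfig | None = None,
                     inputs: np.ndarray | None = None,
                     use_permittivity_only: bool = False,
                     side: float = 0.15,
                     ) -> tuple[MetricsReport, RadialSpectrum, RadialSpectrum]:
    """Score a trained inverter on the test split.

    Returns the per-sample/per-class metric report plus the radial spectra
    of the reconstructions and of the reference profiles.  ``inputs``
    overrides the stored test inputs (e.g. re-noised data for robustness
    studies).  ``model`` is anything with a ``predict(X) -> Y`` method;
    the constant baseline is a plain target vector.
    """
    if config is None:
        config = MeasurementConfig()
    X = ds.inputs[ds.test_idx].astype(float) if inputs is None else inputs
    Y = ds.targets[ds.test_idx].astype(float)
    labels = ds.class_labels[ds.test_idx]
    if hasattr(model, "predict"):
        pred = model.predict(X)
    else:  # constant predictor vector
        pred = np.tile(np.asarray(model, dtype=float), (len(X), 1))

    per_sample = {m: {"eps": np.empty(len(X)), "sigma": np.empty(len(X))}
                  for m in ("ssim", "nrmse", "corr")}
    rec_maps, ref_maps = [], []
    for i in range(len(X)):
        e_est, s_est = devectorize_output(pred[i])
        e_ref, s_ref = devectorize_output(Y[i])
        for chan, est, ref in (("eps", e_est, e_ref),
                               ("sigma", s_est, s_ref)):
            per_sample["ssim"][chan][i] = ssim(est, ref)
            per_sample["nrmse"][chan][i] = nrmse(est, ref)
            per_sample["corr"][chan][i] = corr(est, ref)
        if use_permittivity_only:
            rec_maps.append(e_est.astype(complex))
            ref_maps.append(e_ref.astype(complex))
        else:
            rec_maps.append(complex_permittivity(e_est, s_est, config.omega))
            ref_maps.append(complex_permittivity(e_ref, s_ref, config.omega))

    report = MetricsReport(per_sample=per_sample, class_labels=labels)
    report.aggregate()
    spec_rec = radial_spectrum(mean_power_spectrum(rec_maps), side=side,
                               n_profiles=len(rec_maps))
    spec_ref = radial_spectrum(mean_power_spectrum(ref_maps), side=side,
                               n_profiles=len(ref_maps))
    return report, spec_rec, spec_ref
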