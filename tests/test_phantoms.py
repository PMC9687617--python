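"""Phantom generator: geometry sampling, random-field properties, tissue
segmentation, dielectric assignment, spatial correlation, determinism."""

import numpy as np
import pytest

from mwtbreast import (GeneratorConfig, ImagingGrid, MeasurementConfig,
                       generate_phantom, measure_skin_thickness)
from mwtbreast.phantoms import (ADIPOSE, BACKGROUND, CLASS_FRACTION_TABLE,
                                FIBROGLANDULAR, SKIN, TRANSITIONAL,
                                _ellipse_mask, apply_spatial_correlation,
                                assign_dielectrics, multifractal_field,
                                sample_geometry, segment_tissues)

GRID = ImagingGrid()  # full-resolution 108-pixel grid


class TestGeometry:
    def test_sampled_ranges(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(0)
        geoms = [sample_geometry(cfg, rng) for _ in range(10_000)]
        axes = np.array([[g.axis_a, g.axis_b] for g in geoms])
        thick = np.array([g.skin_thickness for g in geoms])
        centers = np.array([g.center for g in geoms])
        assert axes.min() >= 0.065 and axes.max() <= 0.12
        assert thick.min() >= 0.0015 and thick.max() <= 0.0025
        assert np.hypot(centers[:, 0], centers[:, 1]).max() <= 0.01

    def test_deterministic_given_seed(self):
        cfg = GeneratorConfig()
        g1 = sample_geometry(cfg, np.random.default_rng(5), GRID)
        g2 = sample_geometry(cfg, np.random.default_rng(5), GRID)
        assert g1 == g2

    def test_always_fits_default_domain(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(1)
        half = GRID.side / 2
        for _ in range(500):
            g = sample_geometry(cfg, rng, GRID)
            reach = max(g.axis_a, g.axis_b) / 2
            assert abs(g.center[0]) + reach <= half
            assert abs(g.center[1]) + reach <= half


class TestRandomField:
    def test_standardization(self):
        f = multifractal_field(GRID, np.random.default_rng(3))
        assert abs(f.mean()) < 0.05
        assert abs(f.std() - 1.0) < 0.05

    def test_power_law_spectrum(self):
        """Azimuthally averaged log-spectrum is close to linear in log
        frequency (scale invariance)."""
        f = multifractal_field(GRID, np.random.default_rng(4))
        P = np.abs(np.fft.fft2(f)) ** 2
        fr = np.fft.fftfreq(GRID.n)
        FX, FY = np.meshgrid(fr, fr, indexing="ij")
        r = np.hypot(FX, FY).ravel()
        p = P.ravel()
        bins = np.logspace(np.log10(1.0 / GRID.n), np.log10(0.5), 12)
        idx = np.digitize(r, bins)
        lx, ly = [], []
        for k in range(1, len(bins)):
            sel = idx == k
            if sel.sum() > 3:
                lx.append(np.log(r[sel].mean()))
                ly.append(np.log(p[sel].mean()))
        slope, intercept = np.polyfit(lx, ly, 1)
        pred = np.polyval([slope, intercept], lx)
        ss_res = np.sum((np.array(ly) - pred) ** 2)
        ss_tot = np.sum((np.array(ly) - np.mean(ly)) ** 2)
        assert 1 - ss_res / ss_tot > 0.9
        assert slope < -1.5  # decaying spectrum

    def test_independent_seeds_uncorrelated(self):
        f1 = multifractal_field(GRID, np.random.default_rng(10))
        f2 = multifractal_field(GRID, np.random.default_rng(11))
        assert abs(np.corrcoef(f1.ravel(), f2.ravel())[0, 1]) < 0.05


class TestSegmentation:
    @pytest.mark.parametrize("cls", ["A", "B", "C", "D"])
    def test_fractions_within_class_ranges(self, cls):
        cfg = GeneratorConfig()
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            geom = sample_geometry(cfg, rng, GRID)
            f = multifractal_field(GRID, rng)
            labels, targets = segment_tissues(f, geom, cls, cfg, rng, GRID)
            interior = np.isin(labels, [ADIPOSE, TRANSITIONAL,
                                        FIBROGLANDULAR])
            n_int = interior.sum()
            achieved = {
                "fibroglandular": 100 * (labels == FIBROGLANDULAR).sum()
                / n_int,
                "transitional": 100 * (labels == TRANSITIONAL).sum() / n_int,
                "adipose": 100 * (labels == ADIPOSE).sum() / n_int,
            }
            for tissue, (lo, hi) in CLASS_FRACTION_TABLE[cls].items():
                assert lo - 1 <= achieved[tissue] <= hi + 1
                # achieved matches the drawn target to quantile rounding
                assert abs(achieved[tissue] - targets[tissue]) <= 1.0

    def test_unknown_class_rejected(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(0)
        geom = sample_geometry(cfg, rng, GRID)
        f = multifractal_field(GRID, rng)
        with pytest.raises(ValueError):
            segment_tissues(f, geom, "E", cfg, rng, GRID)

    def test_tiny_interior_rejected(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(0)
        geom = sample_geometry(cfg, rng)
        f = multifractal_field(ImagingGrid(n=16), rng)
        with pytest.raises(RuntimeError):
            segment_tissues(f, geom, "A", cfg, rng, ImagingGrid(n=16))


class TestDielectrics:
    def test_physical_bounds_and_ordering(self):
        cfg = GeneratorConfig()
        mc = MeasurementConfig()
        for seed in range(5):
            p = generate_phantom(cfg, "C", GRID, seed=seed, config=mc)
            tissue = p.tissue_map != BACKGROUND
            assert np.all(p.eps_map[tissue] >= 1.0)
            assert np.all(p.sigma_map >= 0.0)
            assert np.all(np.isfinite(p.eps_map))
            fib = p.eps_map[p.tissue_map == FIBROGLANDULAR].mean()
            adip = p.eps_map[p.tissue_map == ADIPOSE].mean()
            assert fib > adip

    def test_sample_means_match_configured_means(self):
        """Over many pixels, per-tissue means land within 3 standard errors
        of the configured distribution means."""
        cfg = GeneratorConfig(correlation_length=0.0)
        mc = MeasurementConfig()
        rng = np.random.default_rng(0)
        labels = np.full((120, 120), ADIPOSE, dtype=np.int8)
        labels[:, 60:] = FIBROGLANDULAR
        eps, sigma = assign_dielectrics(labels, cfg, rng, mc)
        for lab in (ADIPOSE, FIBROGLANDULAR):
            m, s = cfg.tissue_stats[lab]["eps"]
            vals = eps[labels == lab]
            se = s / np.sqrt(vals.size)
            assert abs(vals.mean() - m) < 3 * se + 0.05  # + truncation bias


class TestSpatialCorrelation:
    def _autocorr_lag1(self, x, mask):
        a = x[mask]
        b = np.roll(x, 1, axis=1)[mask]
        return np.corrcoef(a, b)[0, 1]

    def test_zero_length_is_identity(self):
        cfg = GeneratorConfig()
        mc = MeasurementConfig()
        rng = np.random.default_rng(2)
        labels = np.full((40, 40), ADIPOSE, dtype=np.int8)
        eps, sigma = assign_dielectrics(labels, cfg, rng, mc)
        e2, s2 = apply_spatial_correlation(eps, sigma, labels, 0.0)
        assert np.array_equal(e2, eps) and np.array_equal(s2, sigma)

    def test_smoothing_increases_autocorrelation(self):
        cfg = GeneratorConfig()
        mc = MeasurementConfig()
        rng = np.random.default_rng(2)
        labels = np.full((60, 60), FIBROGLANDULAR, dtype=np.int8)
        eps, sigma = assign_dielectrics(labels, cfg, rng, mc)
        mask = labels == FIBROGLANDULAR
        mask[:, 0] = False  # wrap-around column
        before = self._autocorr_lag1(eps, mask)
        e2, _ = apply_spatial_correlation(eps, sigma, labels, 2.0)
        after = self._autocorr_lag1(e2, mask)
        assert after > before


class TestGeneratePhantom:
    def test_full_determinism(self):
        cfg = GeneratorConfig()
        p1 = generate_phantom(cfg, "B", GRID, seed=99)
        p2 = generate_phantom(cfg, "B", GRID, seed=99)
        assert np.array_equal(p1.tissue_map, p2.tissue_map)
        assert np.array_equal(p1.eps_map, p2.eps_map)
        assert np.array_equal(p1.sigma_map, p2.sigma_map)

    def test_support_confinement(self):
        """No tissue pixel outside the ellipse-plus-skin region."""
        cfg = GeneratorConfig()
        for seed in (3, 4):
            p = generate_phantom(cfg, "A", GRID, seed=seed)
            outer = _ellipse_mask(GRID, p.geometry)
            assert not np.any((p.tissue_map != BACKGROUND) & ~outer)
            assert np.all(p.eps_map[~outer]
                          == MeasurementConfig()
                          .background_rel_permittivity.real)

    def test_skin_forms_closed_annulus(self):
        from scipy.ndimage import binary_fill_holes

        cfg = GeneratorConfig()
        p = generate_phantom(cfg, "C", GRID, seed=11)
        skin = p.tissue_map == SKIN
        filled = binary_fill_holes(skin)
        interior = np.isin(p.tissue_map, [ADIPOSE, TRANSITIONAL,
                                          FIBROGLANDULAR])
        assert np.all(filled[interior])  # annulus encloses the interior

    def test_measured_skin_thickness_close_to_sampled(self):
        cfg = GeneratorConfig()
        for seed in range(8):
            p = generate_phantom(cfg, "B", GRID, seed=200 + seed)
            measured = measure_skin_thickness(p, GRID)
            assert abs(measured - p.geometry.skin_thickness) \
                <= GRID.pixel_size

    def test_class_ordering_of_fibroglandular_content(self):
        """Mean fibroglandular fraction increases from class A to D."""
        cfg = GeneratorConfig()
        means = []
        for cls in "ABCD":
            fr = []
            for seed in range(12):
                p = generate_phantom(cfg, cls, GRID, seed=300 + seed)
                interior = np.isin(p.tissue_map,
                                   [ADIPOSE, TRANSITIONAL, FIBROGLANDULAR])
                fr.append((p.tissue_map == FIBROGLANDULAR).sum()
                          / interior.sum())
            means.append(np.mean(fr))
        assert means[0] < means[1] < means[2] < means[3]
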