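"""Forward-solver unit and property tests (incident fields, operator,
state equation, receivers, noise model)."""

import numpy as np
import pytest
from scipy.special import hankel2

from mwtbreast import (ConvergenceError, GreensOperator, ImagingGrid,
                       MeasurementConfig, add_awgn,
                       assemble_scattering_matrix, incident_field,
                       scattered_at_receivers, solve_total_field)
from mwtbreast.em_forward import ScatteringMatrix
from mwtbreast.green import richmond_coupling


class TestIncidentField:
    def test_radial_symmetry(self, config, small_grid):
        """A line source illuminates equidistant pixels identically."""
        e = incident_field(config, small_grid, view=0)
        src = config.antenna_positions()[0]
        X, Y = small_grid.pixel_centers()
        R = np.hypot(X - src[0], Y - src[1])
        # find two distinct pixels at (numerically) equal distance
        flat = R.ravel()
        order = np.argsort(flat)
        pairs = np.flatnonzero(np.diff(flat[order]) < 1e-12)
        assert len(pairs) > 0
        i, j = order[pairs[0]], order[pairs[0] + 1]
        assert e.ravel()[i] == pytest.approx(e.ravel()[j], abs=1e-14)

    def test_amplitude_decays_as_inverse_sqrt_range(self, config):
        """Far from the source |E_i| follows the 1/sqrt(k rho) Hankel
        asymptotics."""
        k = config.wavenumber.real
        rho = np.linspace(0.3, 3.0, 50)
        exact = np.abs(hankel2(0, k * rho))
        asym = np.sqrt(2.0 / (np.pi * k * rho))
        assert np.allclose(exact, asym, rtol=5e-3)

    def test_view_out_of_range(self, config, small_grid):
        with pytest.raises(IndexError):
            incident_field(config, small_grid, view=config.n_antennas)

    def test_active_background_rejected(self):
        with pytest.raises(ValueError):
            MeasurementConfig(background_rel_permittivity=20 + 1j)


class TestGreensOperator:
    @pytest.mark.parametrize("n", [8, 16])
    def test_fft_equals_dense(self, config, n, rng):
        """Block-Toeplitz FFT application reproduces the dense matrix
        product to round-off."""
        grid = ImagingGrid(n=n)
        op = GreensOperator(grid, config)
        v = rng.normal(size=n * n) + 1j * rng.normal(size=n * n)
        ref = op.dense() @ v
        got = op.apply(v)
        assert np.linalg.norm(got - ref) / np.linalg.norm(ref) < 1e-12

    def test_linearity_and_zero(self, config, small_grid, rng):
        op = GreensOperator(small_grid, config)
        n2 = small_grid.n_pixels
        v1 = rng.normal(size=n2) + 1j * rng.normal(size=n2)
        v2 = rng.normal(size=n2) + 1j * rng.normal(size=n2)
        a, b = 2.0 - 1j, 0.3 + 0.7j
        lhs = op.apply(a * v1 + b * v2)
        rhs = a * op.apply(v1) + b * op.apply(v2)
        assert np.allclose(lhs, rhs, atol=1e-12 * np.linalg.norm(rhs))
        assert np.all(op.apply(np.zeros(n2, dtype=complex)) == 0)

    def test_shape_mismatch(self, config, small_grid):
        op = GreensOperator(small_grid, config)
        with pytest.raises(ValueError):
            op.apply(np.ones(7, dtype=complex))


class TestTotalField:
    def test_zero_contrast_returns_incident(self, config, small_grid):
        e_i = incident_field(config, small_grid, 3)
        op = GreensOperator(small_grid, config)
        e_t = solve_total_field(np.zeros_like(e_i), e_i, op)
        assert np.array_equal(e_t, e_i)

    def test_weak_scatterer_matches_first_born(self, config, small_grid):
        """For |chi| <= 0.01 the total field is the incident field plus the
        single-scattering correction to within 1%."""
        X, Y = small_grid.pixel_centers()
        chi = np.where(np.hypot(X, Y) < 0.04, 0.01, 0.0).astype(complex)
        op = GreensOperator(small_grid, config)
        e_i = incident_field(config, small_grid, 0)
        e_t = solve_total_field(chi, e_i, op, tol=1e-12)
        born = e_i + op.apply(chi * e_i)
        assert np.linalg.norm(e_t - born) / np.linalg.norm(e_t) < 1e-2

    def test_nonconvergence_raises_with_residual(self, config, small_grid):
        X, Y = small_grid.pixel_centers()
        chi = np.where(np.hypot(X, Y) < 0.05, 2.0 - 1.0j, 0).astype(complex)
        e_i = incident_field(config, small_grid, 0)
        op = GreensOperator(small_grid, config)
        with pytest.raises(ConvergenceError) as exc:
            solve_total_field(chi, e_i, op, tol=1e-12, max_iter=1)
        assert exc.value.residual > 0


class TestScatteredField:
    def test_zero_contrast_zero_field(self, config, small_grid):
        e = np.ones((small_grid.n,) * 2, dtype=complex)
        out = scattered_at_receivers(np.zeros_like(e), e, config, small_grid)
        assert out.shape == (config.n_antennas,)
        assert np.all(out == 0)

    def test_single_cell_radiates_hankel_pattern(self, config, small_grid):
        """One excited cell produces the Richmond-weighted H0 pattern."""
        n = small_grid.n
        chi = np.zeros((n, n), dtype=complex)
        e_t = np.zeros((n, n), dtype=complex)
        chi[5, 9] = 0.3 + 0.1j
        e_t[5, 9] = 1.2 - 0.4j
        got = scattered_at_receivers(chi, e_t, config, small_grid)
        X, Y = small_grid.pixel_centers()
        cell = np.array([X[5, 9], Y[5, 9]])
        pos = config.antenna_positions()
        R = np.hypot(pos[:, 0] - cell[0], pos[:, 1] - cell[1])
        a = small_grid.pixel_size / np.sqrt(np.pi)
        expected = richmond_coupling(config.wavenumber, a, R) * chi[5, 9] \
            * e_t[5, 9]
        assert np.allclose(got, expected, rtol=1e-12)

    def test_born_linearity_in_contrast(self, config, small_grid):
        """Doubling a weak contrast approximately doubles the data."""
        X, Y = small_grid.pixel_centers()
        base = np.where(np.hypot(X, Y) < 0.04, 0.005, 0.0).astype(complex)
        out = {}
        for scale in (1.0, 2.0):
            s = assemble_scattering_matrix(scale * base, config, small_grid,
                                           tol=1e-12)
            out[scale] = s.values
        dev = np.linalg.norm(out[2.0] - 2 * out[1.0]) \
            / np.linalg.norm(out[2.0])
        assert dev < 0.05


class TestScatteringMatrix:
    def test_zero_phantom_gives_zero_matrix(self, config, small_grid):
        s = assemble_scattering_matrix(
            np.zeros((small_grid.n,) * 2, dtype=complex), config, small_grid)
        assert np.all(s.values == 0)

    def test_reciprocity_random_phantoms(self, config, small_grid, rng):
        """Coincident transmit/receive positions make S symmetric."""
        from scipy.ndimage import gaussian_filter

        for _ in range(2):
            rough = rng.normal(size=(small_grid.n,) * 2)
            chi = 0.3 * np.abs(gaussian_filter(rough, 2)) \
                * (1.0 - 0.2j)
            s = assemble_scattering_matrix(chi.astype(complex), config,
                                           small_grid, tol=1e-10)
            asym = np.linalg.norm(s.values - s.values.T) \
                / np.linalg.norm(s.values)
            assert asym < 1e-6

    def test_born_limit_error_decreases_with_contrast(self, config,
                                                      small_grid):
        """The Born linearization error vanishes monotonically as the
        contrast scale shrinks."""
        X, Y = small_grid.pixel_centers()
        shape = np.where(np.hypot(X - 0.01, Y) < 0.04, 1.0, 0.0)
        op = GreensOperator(small_grid, config)
        coupling_err = []
        for scale in (1e-1, 1e-2, 1e-3):
            chi = (scale * shape).astype(complex)
            s_full = assemble_scattering_matrix(chi, config, small_grid,
                                                tol=1e-12).values
            s_born = np.empty_like(s_full)
            for v in range(config.n_antennas):
                e_i = incident_field(config, small_grid, v)
                s_born[v] = scattered_at_receivers(chi, e_i, config,
                                                   small_grid)
            coupling_err.append(np.linalg.norm(s_full - s_born)
                                / np.linalg.norm(s_full))
        assert coupling_err[0] > coupling_err[1] > coupling_err[2]

    def test_energy_bounded_for_lossless_background(self, config,
                                                    small_grid, rng):
        from scipy.ndimage import gaussian_filter

        power = []
        for k in range(3):
            chi = 0.5 * np.abs(gaussian_filter(
                rng.normal(size=(small_grid.n,) * 2), 2)).astype(complex)
            s = assemble_scattering_matrix(chi, config, small_grid)
            power.append(np.sum(np.abs(s.values) ** 2))
        assert np.all(np.isfinite(power))
        assert max(power) < 1e6


class TestNoiseModel:
    def test_infinite_snr_is_identity(self, rng):
        s = ScatteringMatrix(rng.normal(size=(30, 30))
                             + 1j * rng.normal(size=(30, 30)))
        out = add_awgn(s, np.inf, seed=1)
        assert out is s

    def test_same_seed_reproduces_noise(self, rng):
        s = ScatteringMatrix(rng.normal(size=(30, 30))
                             + 1j * rng.normal(size=(30, 30)))
        a = add_awgn(s, 20.0, seed=123)
        b = add_awgn(s, 20.0, seed=123)
        assert np.array_equal(a.values, b.values)
        assert a.snr_db == 20.0 and a.noise_seed == 123

    def test_empirical_snr_calibration(self, rng):
        """Monte-Carlo SNR over many draws matches the request to 0.1 dB."""
        s = ScatteringMatrix(rng.normal(size=(30, 30))
                             + 1j * rng.normal(size=(30, 30)))
        p_sig = np.mean(np.abs(s.values) ** 2)
        target = 30.0
        noise_power = []
        for seed in range(10_000):
            noisy = add_awgn(s, target, seed=seed)
            noise_power.append(np.mean(np.abs(noisy.values - s.values) ** 2))
        snr_emp = 10 * np.log10(p_sig / np.mean(noise_power))
        assert abs(snr_emp - target) < 0.1
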