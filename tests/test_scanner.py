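"""Continuous scanner physics: trajectory, Langevin response, PSF tensor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fflmpi.scanner import (ParticleModel, RasterSpec, ScannerModel,
                            drive_field, ffl_position, ffl_velocity, langevin,
                            langevin_derivative, langevin_over_argument,
                            magnetic_field, psf_tensor, psf_tensor_grid)


class TestLangevin:
    def test_known_values(self):
        assert langevin(0.0) == 0.0
        assert langevin(1.0) == pytest.approx(1 / np.tanh(1) - 1, rel=1e-12)
        # saturation
        assert langevin(50.0) == pytest.approx(1 - 1 / 50, rel=1e-10)

    def test_small_argument_series(self):
        a = 1e-4
        assert langevin(a) == pytest.approx(a / 3, rel=1e-9)

    def test_series_crossover_continuous(self):
        a = 1e-3  # crossover point of the series/closed-form switch
        below = langevin(a * (1 - 1e-9))
        above = langevin(a * (1 + 1e-9))
        assert abs(above - below) < 1e-12

    @given(st.floats(min_value=1e-6, max_value=60.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_and_odd_symmetry(self, a):
        val = langevin(a)
        assert 0 <= val < 1
        assert langevin(-a) == -val

    @given(st.floats(min_value=1e-3, max_value=20.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone(self, a):
        assert langevin(a * 1.01) > langevin(a)

    def test_derivative_limits(self):
        assert langevin_derivative(0.0) == pytest.approx(1 / 3, abs=1e-14)
        assert langevin_derivative(1.0) == pytest.approx(
            1 - 1 / np.sinh(1) ** 2, rel=1e-12)

    @given(st.floats(min_value=1e-3, max_value=30.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_derivative_matches_finite_difference(self, a):
        h = 1e-6 * max(1.0, a)
        fd = (langevin(a + h) - langevin(a - h)) / (2 * h)
        assert langevin_derivative(a) == pytest.approx(fd, rel=1e-7, abs=1e-8)

    def test_over_argument_limit(self):
        assert langevin_over_argument(0.0) == pytest.approx(1 / 3, abs=1e-14)
        assert langevin_over_argument(2.0) == pytest.approx(
            langevin(2.0) / 2.0, rel=1e-12)


class TestTrajectory:
    def test_drive_starts_at_isocenter(self, tiny_scanner):
        xi = ffl_position(tiny_scanner, 0.0)
        np.testing.assert_allclose(xi, [0.0, 0.0], atol=1e-15)

    def test_drive_peak_excursion(self, tiny_scanner):
        # quarter period: peak of the sine, displacement A/G0
        t = 1 / (4 * tiny_scanner.drive_frequency)
        xi = ffl_position(tiny_scanner, t)
        assert xi[0] == pytest.approx(0.0, abs=1e-15)
        assert xi[1] == pytest.approx(
            tiny_scanner.drive_amplitude / tiny_scanner.gradient, rel=1e-12)

    def test_excursion_for_momentum_parameters(self):
        # 5 mT drive over a 5.7 T/m gradient: ~0.877 mm peak displacement
        sc = ScannerModel(raster=None, scan_duration=1e-3)
        assert sc.drive_excursion == pytest.approx(5e-3 / 5.7, rel=1e-12)
        assert sc.drive_excursion == pytest.approx(0.877e-3, rel=1e-2)

    def test_velocity_at_peak_and_zero(self, tiny_scanner):
        f0 = tiny_scanner.drive_frequency
        v0 = ffl_velocity(tiny_scanner, 0.0)
        expect = 2 * np.pi * f0 * tiny_scanner.drive_excursion
        assert v0[1] == pytest.approx(expect, rel=1e-12)
        vq = ffl_velocity(tiny_scanner, 1 / (4 * f0))
        assert abs(vq[1]) < expect * 1e-9

    def test_velocity_matches_finite_difference(self, raster_scanner):
        rng = np.random.default_rng(7)
        t = rng.uniform(1e-6, raster_scanner.duration - 1e-6, 1000)
        # keep clear of the raster turn points where v jumps
        lp = raster_scanner.raster.line_period
        dist = np.abs(t / lp - np.round(t / lp)) * lp
        t = t[dist > 1e-5]
        h = 1e-9
        fd = (ffl_position(raster_scanner, t + h)
              - ffl_position(raster_scanner, t - h)) / (2 * h)
        v = ffl_velocity(raster_scanner, t)
        np.testing.assert_allclose(v, fd, rtol=1e-6, atol=1e-6)

    def test_raster_zigzag_shape(self):
        r = RasterSpec(n_lines=4, line_period=1e-3, x_extent=0.02, z_extent=0.01)
        x, z = r.position(np.array([0.0, 0.5e-3, 1.0e-3, 1.5e-3, 4e-3]))
        # fast axis sweeps -X/2 -> X/2 -> -X/2 ...
        np.testing.assert_allclose(
            x, [-0.01, 0.0, 0.01, 0.0, -0.01], atol=1e-15)
        # slow axis ramps linearly over the whole scan
        assert z[0] == pytest.approx(-0.005)
        assert z[-1] == pytest.approx(0.005)


class TestMagneticField:
    def test_field_free_line_nullity(self, raster_scanner):
        # H vanishes on the whole line {xi(t) + s * y_hat}
        rng = np.random.default_rng(3)
        for t in rng.uniform(0, raster_scanner.duration, 50):
            xi = ffl_position(raster_scanner, t)
            for s in (-0.02, 0.0, 0.013):
                x = np.array([xi[0], s, xi[1]])
                h = magnetic_field(raster_scanner, x, t)
                assert np.linalg.norm(h) <= 1e-12

    def test_transverse_offset_gives_gradient_field(self, tiny_scanner):
        t = 0.37 * tiny_scanner.duration
        xi = ffl_position(tiny_scanner, t)
        delta = 1.3e-3
        x = np.array([xi[0] + delta, 0.0, xi[1]])
        h = magnetic_field(tiny_scanner, x, t)
        np.testing.assert_allclose(
            h, [tiny_scanner.gradient * delta, 0.0, 0.0], atol=1e-15)

    def test_y_component_always_zero(self, raster_scanner):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.uniform(-0.01, 0.01, 3)
            t = rng.uniform(0, raster_scanner.duration)
            assert magnetic_field(raster_scanner, x, t)[1] == 0.0

    def test_time_outside_scan_raises(self, tiny_scanner):
        with pytest.raises(ValueError, match="scan duration"):
            magnetic_field(tiny_scanner, np.zeros(3), tiny_scanner.duration + 1e-3)

    def test_drive_field_consistent_with_trajectory(self, tiny_scanner):
        # Eq. H = H_D - G x at x = 0 reduces to H_D = G xi
        t = 0.21 * tiny_scanner.duration
        hd = drive_field(tiny_scanner, t)
        h0 = magnetic_field(tiny_scanner, np.zeros(3), t)
        np.testing.assert_allclose(hd, h0, atol=1e-18)


class TestPsfTensor:
    def test_isotropic_limit_on_ffl(self, tiny_scanner, particle):
        # offsets along the FFL give zero field: h = (beta/3) G
        expect = (particle.beta / 3) * tiny_scanner.gradient_matrix
        for s in (0.0, 0.004, -0.011):
            h = psf_tensor(tiny_scanner, particle, np.array([0.0, s, 0.0]))
            np.testing.assert_allclose(h, expect, rtol=1e-10, atol=1e-12)

    def test_ffl_axis_rows_and_columns_vanish(self, tiny_scanner, particle):
        rng = np.random.default_rng(5)
        for _ in range(10):
            u = rng.uniform(-5e-3, 5e-3, 3)
            h = psf_tensor(tiny_scanner, particle, u)
            np.testing.assert_allclose(h[1, :], 0.0, atol=1e-30)
            np.testing.assert_allclose(h[:, 1], 0.0, atol=1e-30)

    def test_saturation_decay(self, tiny_scanner, particle):
        # L' -> 0 and L/|w| -> 1/|w| as the field saturates, so the
        # kernel decays (like 1/r) away from the FFL
        mags = [np.abs(psf_tensor(tiny_scanner, particle, [d, 0, d])).max()
                for d in (1e-4, 0.01, 0.1, 1.0)]
        assert all(a > b for a, b in zip(mags, mags[1:]))
        assert mags[-1] < 1e-3 * mags[0]

    def test_grid_form_matches_pointwise(self, tiny_scanner, particle):
        ux = np.array([-2e-3, 0.0, 1e-3])
        uz = np.array([5e-4, -1e-3])
        h = psf_tensor_grid(tiny_scanner, particle, ux[:, None], uz[None, :])
        for i, x in enumerate(ux):
            for j, z in enumerate(uz):
                single = psf_tensor(tiny_scanner, particle, [x, 0.0, z])
                np.testing.assert_allclose(h[:, :, i, j], single,
                                           rtol=1e-12, atol=1e-20)

    def test_tensor_reproduces_magnetization_derivative(self, tiny_scanner,
                                                        particle):
        """Brute-force oracle: the analytic kernel chain must equal the
        numeric time-derivative of the Langevin magnetization of a point
        source over one drive period."""
        sc = tiny_scanner
        src = np.array([0.6e-3, 0.0, -0.4e-3])
        n = 2048
        t = np.linspace(1e-9, 1 / sc.drive_frequency, n, endpoint=False) \
            + 2 / sc.drive_frequency
        dt = 1e-10

        def bz_moment(tv):
            out = np.empty(tv.size)
            for i, ti in enumerate(tv):
                h = magnetic_field(sc, src, ti)
                hn = np.linalg.norm(h)
                if hn == 0:
                    out[i] = 0.0
                else:
                    out[i] = particle.moment * langevin(particle.beta * hn) \
                        * h[2] / hn
            return out

        numeric = (bz_moment(t + dt) - bz_moment(t - dt)) / (2 * dt)
        xi = ffl_position(sc, t)
        v = ffl_velocity(sc, t)
        analytic = np.empty(n)
        for i in range(n):
            u = np.array([xi[0][i] - src[0], 0.0, xi[1][i] - src[2]])
            h = psf_tensor(sc, particle, u)
            analytic[i] = particle.moment * (h[2, 0] * v[0][i]
                                             + h[2, 2] * v[1][i])
        err = np.linalg.norm(analytic - numeric) / np.linalg.norm(numeric)
        assert err <= 1e-4


class TestValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ScannerModel(gradient=-1.0)
        with pytest.raises(ValueError):
            ScannerModel(drive_axis="y")
        with pytest.raises(ValueError):
            ParticleModel(moment=-1e-18)
        with pytest.raises(ValueError):
            # Nyquist violated for the retained harmonics
            ScannerModel(sample_rate=100e3, max_harmonic=5)

    def test_gradient_matrix_structure(self):
        sc = ScannerModel(raster=None, scan_duration=1e-3)
        np.testing.assert_array_equal(
            sc.gradient_matrix, np.diag([-5.7, 0.0, 5.7]))

    def test_config_round_trip(self, raster_scanner, particle):
        sc2 = ScannerModel.from_dict(raster_scanner.to_dict())
        assert sc2 == raster_scanner
        assert ParticleModel.from_dict(particle.to_dict()) == particle
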