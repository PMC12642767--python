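"""Discrete forward operators: adjoints, algebraic identities, compression."""

import numpy as np
import pytest

from fflmpi.grids import ImageGrid
from fflmpi.linops import Compose, DenseMap, dot_test
from fflmpi.operators import (HarmonicSelector, NotchFilter, TimeSignal,
                              bilinear_matrix, build_projection_model,
                              energy_retention, gamma_transfer)
from fflmpi.scanner import ffl_position


class TestAdjoints:
    """Randomized complex dot tests: |<Ax,y> - <x,A^H y>|/(||Ax|| ||y||)."""

    def test_component_operators(self, tiny_model, rng):
        ops = {
            "B": tiny_model.B,
            "H": tiny_model.H,
            "E": tiny_model.E,
            "V": tiny_model.V,
            "Gamma": tiny_model.gamma,
            "SF": Compose([tiny_model.S, tiny_model.F]),
            "ADC": tiny_model.compressed,
            "M": tiny_model.time_model,
        }
        for name, op in ops.items():
            err = dot_test(op, rng, n_draws=20)
            assert err <= 1e-8, f"{name}: adjoint error {err:.2e}"


class TestReceiveWeight:
    def test_homogeneous_unit_sensitivity(self, tiny_model, tiny_grid):
        rho = np.arange(tiny_grid.n_cells, dtype=float)
        out = tiny_model.B.forward(rho).reshape(3, -1)
        # z-drive scanner: only the z component carries the image
        np.testing.assert_array_equal(out[0], 0.0)
        np.testing.assert_array_equal(out[1], 0.0)
        np.testing.assert_array_equal(out[2], rho)

    def test_zero_in_zero_out(self, tiny_model, tiny_grid):
        out = tiny_model.B.forward(np.zeros(tiny_grid.n_cells))
        assert not np.any(out)


class TestPSFConvolution:
    def test_delta_image_reproduces_kernel(self, tiny_model, tiny_grid):
        nx, nz = tiny_grid.shape
        delta = np.zeros((3, nx, nz))
        delta[2, nx // 2, nz // 2] = 1.0
        out = tiny_model.H.forward(delta.reshape(-1)).reshape(3, 3, nx, nz)
        ker = tiny_model.H.kernels
        kc = ((ker.shape[2] - 1) // 2, (ker.shape[3] - 1) // 2)
        # C_zz around the delta equals the sampled kernel around its center
        for di in (-2, 0, 3):
            for dj in (-1, 0, 2):
                assert out[2, 2, nx // 2 + di, nz // 2 + dj] == pytest.approx(
                    ker[2, 2, kc[0] + di, kc[1] + dj], rel=1e-12, abs=1e-18)

    def test_matches_direct_spatial_convolution(self, tiny_scanner, particle,
                                                rng):
        grid = ImageGrid((8, 8), (1.5e-3, 1.5e-3))
        m = build_projection_model(grid, tiny_scanner, particle, K=5,
                                   bandwidth=30e3, kernel_truncation=0.0)
        x = rng.standard_normal(3 * 64)
        got = m.H.forward(x).reshape(3, 3, 8, 8)
        imgs = x.reshape(3, 8, 8)
        ker = m.H.kernels  # (3,3,15,15), center at (7,7)
        brute = np.zeros((3, 3, 8, 8))
        for i in range(3):
            for j in range(3):
                for p in range(8):
                    for q in range(8):
                        acc = 0.0
                        for a in range(8):
                            for b in range(8):
                                acc += imgs[i, a, b] * ker[i, j, p - a + 7,
                                                           q - b + 7]
                        brute[i, j, p, q] = acc
        assert np.linalg.norm(got - brute) <= 1e-10 * np.linalg.norm(brute)

    def test_ffl_axis_channels_are_zero(self, tiny_model, rng):
        x = rng.standard_normal(tiny_model.H.dom_size)
        out = tiny_model.H.forward(x).reshape(3, 3, *tiny_model.grid.shape)
        assert not np.any(out[1, :])
        assert not np.any(out[:, 1])


class TestTrajectorySampler:
    def test_constant_image_gives_constant_series(self, tiny_model):
        c = 2.75
        x = np.full(tiny_model.E.dom_size, c)
        out = tiny_model.E.forward(x).reshape(9, -1)
        # tiny scanner trajectory stays inside the grid: exact constant
        np.testing.assert_allclose(out, c, rtol=1e-12)

    def test_nodes_hit_exactly(self, tiny_grid, tiny_scanner, rng):
        img = rng.standard_normal(tiny_grid.shape)
        pts = np.array([[tiny_grid.axis_coords(0)[3], tiny_grid.axis_coords(0)[7]],
                        [tiny_grid.axis_coords(1)[5], tiny_grid.axis_coords(1)[0]]])
        W = bilinear_matrix(tiny_grid, pts)
        out = W @ img.reshape(-1)
        assert out[0] == pytest.approx(img[3, 5], rel=1e-14)
        assert out[1] == pytest.approx(img[7, 0], rel=1e-14)

    def test_out_of_grid_points_contribute_zero(self, tiny_grid):
        pts = np.array([[1.0, -1.0], [0.0, 0.0]])  # 1 m away
        W = bilinear_matrix(tiny_grid, pts)
        assert W.nnz == 0 or np.abs(W).sum() == 0


class TestVelocityWeight:
    def test_zero_velocity_zero_signal(self, tiny_model, rng):
        x = rng.standard_normal(tiny_model.V.dom_size)
        v_saved = tiny_model.V.velocity.copy()
        try:
            tiny_model.V.velocity[:] = 0.0
            assert not np.any(tiny_model.V.forward(x))
        finally:
            tiny_model.V.velocity[:] = v_saved

    def test_linear_in_moment_and_input(self, tiny_model, rng):
        x = rng.standard_normal(tiny_model.V.dom_size)
        out = tiny_model.V.forward(x)
        np.testing.assert_allclose(tiny_model.V.forward(2 * x), 2 * out,
                                   rtol=1e-14)


class TestNotchFilter:
    def test_tone_at_fundamental_removed(self, tiny_scanner):
        n = tiny_scanner.n_samples
        t = tiny_scanner.time_samples()
        tone = np.sin(2 * np.pi * tiny_scanner.drive_frequency * t)
        g = NotchFilter(gamma_transfer(tiny_scanner, n))
        out = g.forward(tone)
        assert np.abs(out).max() < 1e-12

    def test_tone_outside_notch_unchanged(self, tiny_scanner):
        n = tiny_scanner.n_samples
        t = tiny_scanner.time_samples()
        tone = np.cos(2 * np.pi * 3 * tiny_scanner.drive_frequency * t)
        g = NotchFilter(gamma_transfer(tiny_scanner, n))
        np.testing.assert_allclose(g.forward(tone), tone, atol=1e-12)

    def test_real_input_gives_real_output(self, tiny_scanner, rng):
        g = NotchFilter(gamma_transfer(tiny_scanner, tiny_scanner.n_samples))
        out = g.forward(rng.standard_normal(g.dom_size))
        assert np.isrealobj(out)


class TestHarmonicSelector:
    def test_band_membership_matches_brute_force(self, tiny_scanner):
        n = tiny_scanner.n_samples
        fs = tiny_scanner.sample_rate
        f0 = tiny_scanner.drive_frequency
        bw = 30e3
        sel = HarmonicSelector(n, fs, f0, 5, bw)
        freqs = np.fft.fftfreq(n, 1 / fs)
        count = 0
        for k in range(2, 6):
            for i, f in enumerate(freqs):
                if f > 0 and abs(f - k * f0) <= bw / 2:
                    count += 1
                    assert i in sel.band_index_map[k]
        assert count == sel.indices.size

    def test_in_band_energy_retained(self, tiny_scanner):
        n = tiny_scanner.n_samples
        t = tiny_scanner.time_samples()
        f0 = tiny_scanner.drive_frequency
        # an exact DFT bin 10 kHz above harmonic 2, inside the 30 kHz band
        sig = np.sin(2 * np.pi * (2 * f0 + 10e3) * t)
        ret = energy_retention(sig, tiny_scanner, K=5, bandwidth=30e3)
        assert ret == pytest.approx(1.0, abs=1e-6)

    def test_fundamental_excluded(self, tiny_scanner):
        n = tiny_scanner.n_samples
        t = tiny_scanner.time_samples()
        sig = np.sin(2 * np.pi * tiny_scanner.drive_frequency * t)
        sel = HarmonicSelector(n, tiny_scanner.sample_rate,
                               tiny_scanner.drive_frequency, 5, 30e3)
        coeffs = sel.forward(np.fft.fft(sig))
        assert np.abs(coeffs).max() < 1e-9 * n

    def test_selector_times_adjoint_is_identity(self, tiny_scanner, rng):
        sel = HarmonicSelector(tiny_scanner.n_samples, tiny_scanner.sample_rate,
                               tiny_scanner.drive_frequency, 5, 30e3)
        y = rng.standard_normal(sel.ran_size) + 1j * rng.standard_normal(sel.ran_size)
        np.testing.assert_allclose(sel.forward(sel.adjoint(y)), y, rtol=1e-15)

    def test_nyquist_violation_rejected(self, tiny_scanner):
        with pytest.raises(ValueError, match="Nyquist"):
            HarmonicSelector(1000, 200e3, 45e3, 5, 500.0)

    def test_compression_ratio_accounting(self, tiny_model, rng):
        blk = tiny_model.make_block(
            rng.standard_normal(tiny_model.S.ran_size).astype(complex))
        expect = (blk.n_coefficients * 16) / (blk.n_samples * 8)
        assert blk.compression_ratio() == expect


class TestAssembledModels:
    def test_zero_density_zero_signal(self, tiny_model):
        out = tiny_model.compressed.forward(np.zeros(tiny_model.B.dom_size))
        assert not np.any(out)

    def test_superposition_and_scaling(self, tiny_model, rng):
        x1 = rng.standard_normal(tiny_model.B.dom_size)
        x2 = rng.standard_normal(tiny_model.B.dom_size)
        M = tiny_model.time_model
        lhs = M.forward(x1 + 0.5 * x2)
        rhs = M.forward(x1) + 0.5 * M.forward(x2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10 * np.abs(rhs).max())

    def test_single_fft_form_equals_filtered_fft_form(self, tiny_model, rng):
        """The compressed operator with the transfer folded into the
        spectral diagonal must equal select(F(notch-filtered signal))."""
        for _ in range(5):
            x = rng.standard_normal(tiny_model.B.dom_size)
            a = tiny_model.compressed.forward(x)
            b = tiny_model.compressed_via_gamma.forward(x)
            assert np.linalg.norm(a - b) <= 1e-10 * np.linalg.norm(b)

    def test_velocity_scales_with_moment(self, tiny_grid, tiny_scanner,
                                         particle, rng):
        import dataclasses
        m2 = dataclasses.replace(particle, moment=2 * particle.moment)
        mod1 = build_projection_model(tiny_grid, tiny_scanner, particle,
                                      K=5, bandwidth=30e3)
        mod2 = build_projection_model(tiny_grid, tiny_scanner, m2,
                                      K=5, bandwidth=30e3)
        x = rng.standard_normal(tiny_grid.n_cells)
        np.testing.assert_allclose(mod2.signal.forward(x),
                                   2 * mod1.signal.forward(x), rtol=1e-12)


class TestDenseOracleHelpers:
    def test_dot_test_on_dense_map(self, rng):
        a = rng.standard_normal((7, 5)) + 1j * rng.standard_normal((7, 5))
        assert dot_test(DenseMap(a), rng) < 1e-14
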