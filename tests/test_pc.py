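"""Log-Gabor filter bank and oriented phase congruency."""

import numpy as np
import pytest

from pcbp import (
    PhantomSpec,
    boundary_band,
    build_log_gabor_bank,
    make_phantom,
    noise_threshold,
    oriented_pc,
    overall_pc,
    quadrature_responses,
    spread_weight,
)


def circular_convolve(image, kernel):
    """Brute-force periodic convolution: out[i,j] = sum h[k,l] I[i-k, j-l]."""
    out = np.zeros(image.shape, dtype=complex)
    for k in range(kernel.shape[0]):
        for l in range(kernel.shape[1]):
            out += kernel[k, l] * np.roll(image, (k, l), axis=(0, 1))
    return out


class TestBank:
    def test_default_bank_has_48_filters_all_dc_free(self):
        bank = build_log_gabor_bank(128, 128, n_scales=6, n_orientations=8)
        flat = [t for row in bank.transfer for t in row]
        assert len(flat) == 48
        for t in flat:
            assert t[0, 0] == 0.0
            assert np.all(t >= 0)
            assert np.isrealobj(t)

    def test_single_filter_peaks_near_unity_at_center_frequency(self):
        # dense frequency grid: the radial profile maximum is 1 at 1/lambda_min
        bank = build_log_gabor_bank(256, 256, n_scales=1, n_orientations=1)
        t = bank.transfer[0][0]
        assert 0.98 < t.max() <= 1.0
        peak = np.unravel_index(np.argmax(t), t.shape)
        f_peak = np.hypot(
            np.fft.fftfreq(256)[peak[0]], np.fft.fftfreq(256)[peak[1]]
        )
        assert f_peak == pytest.approx(1.0 / bank.wavelength_min, rel=0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rows": 4, "cols": 64},
            {"rows": 64, "cols": 64, "n_scales": 0},
            {"rows": 64, "cols": 64, "n_orientations": 0},
            {"rows": 64, "cols": 64, "wavelength_min": 1.0},
            {"rows": 64, "cols": 64, "mult": 1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_log_gabor_bank(**kwargs)


class TestQuadrature:
    def test_constant_image_gives_zero_response(self):
        bank = build_log_gabor_bank(32, 32, n_scales=2, n_orientations=2)
        resp = quadrature_responses(np.full((32, 32), 0.7), bank)
        assert np.allclose(resp.amplitude, 0.0, atol=1e-12)

    def test_amplitude_is_quadrature_norm(self, rng):
        bank = build_log_gabor_bank(32, 32, n_scales=3, n_orientations=4)
        resp = quadrature_responses(rng.random((32, 32)), bank)
        assert np.allclose(resp.amplitude**2, resp.even**2 + resp.odd**2)
        assert np.all(resp.phase > -np.pi) and np.all(resp.phase <= np.pi)

    def test_fft_filtering_matches_direct_spatial_convolution(self, rng):
        # frequency/spatial equivalence with periodic boundary, one filter
        bank = build_log_gabor_bank(32, 32, n_scales=2, n_orientations=3)
        image = rng.random((32, 32))
        resp = quadrature_responses(image, bank)
        kernel = np.fft.ifft2(bank.transfer[1][2])
        direct = circular_convolve(image, kernel)
        assert np.allclose(resp.even[1, 2], direct.real, atol=1e-8)
        assert np.allclose(resp.odd[1, 2], direct.imag, atol=1e-8)

    def test_impulse_amplitude_equals_kernel_envelope(self):
        bank = build_log_gabor_bank(32, 32, n_scales=2, n_orientations=2)
        impulse = np.zeros((32, 32))
        impulse[16, 16] = 1.0
        resp = quadrature_responses(impulse, bank)
        kernel = np.fft.ifft2(bank.transfer[0][1])
        expected = np.abs(np.roll(kernel, (16, 16), axis=(0, 1)))
        assert np.allclose(resp.amplitude[0, 1], expected, atol=1e-10)

    def test_shape_mismatch_raises(self):
        bank = build_log_gabor_bank(32, 32, n_scales=1, n_orientations=1)
        with pytest.raises(ValueError):
            quadrature_responses(np.zeros((16, 16)), bank)


class TestSpreadWeight:
    def test_single_scale_concentration_is_penalized(self):
        amps = np.zeros((6, 4, 4))
        amps[2] = 1.0  # all response in one scale
        w = spread_weight(amps)
        assert w == pytest.approx(1.0 / (1.0 + np.exp(10 * (0.4 - 1 / 6))), abs=1e-3)
        assert w == pytest.approx(0.088, abs=2e-3)

    def test_uniform_spread_is_rewarded(self):
        w = spread_weight(np.full((6, 4, 4), 0.5))
        assert w == pytest.approx(1.0 / (1.0 + np.exp(-6.0)), abs=1e-3)

    def test_zero_amplitude_limit(self):
        w = spread_weight(np.zeros((6, 4, 4)))
        assert np.allclose(w, 1.0 / (1.0 + np.exp(10 * 0.4)))


class TestNoiseThreshold:
    def test_disabled_compensation_is_zero(self, rng):
        assert noise_threshold(rng.random((16, 16)), 6, 2.1, k_noise=0) == 0.0

    def test_threshold_scales_linearly_with_amplitude(self, rng):
        amp = rng.random((32, 32))
        t1 = noise_threshold(amp, 6, 2.1, k_noise=2.0)
        t3 = noise_threshold(3.0 * amp, 6, 2.1, k_noise=2.0)
        assert t1 > 0
        assert t3 == pytest.approx(3.0 * t1, rel=1e-12)

    def test_white_noise_pc_suppressed_almost_everywhere(self, rng):
        bank = build_log_gabor_bank(128, 128)
        image = rng.standard_normal((128, 128))
        stack = oriented_pc(image, bank, k_noise=2.0)
        assert np.mean(stack.pc < 0.05) >= 0.95


class TestOrientedPC:
    def test_constant_image_yields_zero_pc(self):
        bank = build_log_gabor_bank(32, 32, n_scales=3, n_orientations=4)
        stack = oriented_pc(np.full((32, 32), 0.3), bank)
        assert stack.pc.shape == (4, 32, 32)
        assert np.allclose(stack.pc, 0.0)

    def test_pc_bounded_by_unit_interval(self, rng):
        bank = build_log_gabor_bank(64, 64)
        for _ in range(5):
            stack = oriented_pc(rng.random((64, 64)), bank)
            assert stack.pc.min() >= 0.0
            assert stack.pc.max() <= 1.0

    def test_step_edge_localized_in_aligned_channel(self):
        step = np.full((64, 64), 0.2)
        step[:, 32:] = 0.8
        bank = build_log_gabor_bank(64, 64)
        stack = oriented_pc(step, bank, k_noise=0)
        energies = stack.pc.sum(axis=(1, 2))
        assert int(np.argmax(energies)) == 0  # channel 0 <-> vertical edges
        # away from the periodic wrap-around edge, every row peaks at the step
        interior = stack.pc[0][:, 8:56]
        cols = np.argmax(interior, axis=1) + 8
        assert np.all(np.abs(cols - 32) <= 1)

    def test_linear_gray_scale_invariance_without_noise_compensation(self, rng):
        bank = build_log_gabor_bank(48, 48)
        image = rng.random((48, 48))
        ref = oriented_pc(image, bank, k_noise=0).pc
        for a, b in [(2.0, 0.0), (0.5, 0.25), (113.0, -7.0)]:
            out = oriented_pc(a * image + b, bank, k_noise=0).pc
            assert np.allclose(out, ref, atol=1e-6)

    def test_rotating_stripes_by_pi_over_o_shifts_dominant_channel(self):
        n_orient = 4
        bank = build_log_gabor_bank(96, 96, n_scales=3, n_orientations=n_orient)
        y, x = np.mgrid[0:96, 0:96].astype(float)

        def dominant(angle):
            stripes = 0.5 + 0.4 * np.sin(
                2 * np.pi * (x * np.cos(angle) - y * np.sin(angle)) / 8.0
            )
            resp = quadrature_responses(stripes, bank)
            return int(np.argmax(resp.amplitude.sum(axis=(0, 2, 3))))

        channels = [dominant(o * np.pi / n_orient) for o in range(n_orient)]
        assert sorted(channels) == list(range(n_orient))
        assert channels[1:] == [(c + 1) % n_orient for c in channels[:-1]]


class TestOverallPC:
    def test_zero_stack_sums_to_zero_and_bound_holds(self):
        bank = build_log_gabor_bank(32, 32, n_scales=2, n_orientations=8)
        stack = oriented_pc(np.zeros((32, 32)), bank)
        assert np.allclose(overall_pc(stack), 0.0)
        stack.pc = np.ones_like(stack.pc)
        assert np.all(overall_pc(stack) <= 8.0 + 1e-12)

    def test_benign_phantom_boundary_carries_the_pc_energy(self, benign_phantom):
        image = benign_phantom.image
        bank = build_log_gabor_bank(*image.shape)
        total = overall_pc(oriented_pc(image, bank))
        band = boundary_band(benign_phantom.tumor_mask, width=4)
        assert total[band].mean() > total[~band].mean()
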