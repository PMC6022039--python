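"""MPEG-7-style descriptors: spectral moments, LPC formants, pitch,
harmonicity."""

import numpy as np
import pytest
import scipy.signal

from anuracall.mpeg7 import (DEFAULT_PITCH_BAND, LpcModel,
                             MPEG7_FEATURE_NAMES, formants_from_lpc,
                             harmonic_descriptors, harmonicity_descriptors,
                             lpc_fit, mpeg7_features, pitch_estimate,
                             spectral_descriptors)

RATE = 8000.0


class TestSpectralDescriptors:
    def test_two_equal_bins_moments(self):
        freqs = np.arange(0, 4001, 10.0)
        power = np.zeros_like(freqs)
        power[freqs == 1000.0] = 2.0
        power[freqs == 3000.0] = 2.0
        total, relevant, centroid, dispersion, _ = spectral_descriptors(
            power, freqs, (0, 4000))
        assert total == pytest.approx(4.0)
        assert relevant == pytest.approx(4.0)
        assert centroid == pytest.approx(2000.0)
        assert dispersion == pytest.approx(1000.0)

    def test_point_mass_has_zero_dispersion(self):
        freqs = np.arange(0, 4001, 10.0)
        power = np.zeros_like(freqs)
        power[freqs == 1500.0] = 1.0
        _, _, centroid, dispersion, _ = spectral_descriptors(
            power, freqs, (0, 4000))
        assert centroid == pytest.approx(1500.0)
        assert dispersion == pytest.approx(0.0)

    def test_flat_spectrum_flatness_one(self):
        freqs = np.arange(0, 4001, 10.0)
        out = spectral_descriptors(np.ones_like(freqs), freqs, (0, 4000))
        assert out[4] == pytest.approx(1.0)

    def test_relevant_power_bounded_by_total(self):
        rng = np.random.default_rng(0)
        freqs = np.arange(0, 4001, 10.0)
        power = rng.uniform(0, 1, freqs.size)
        out = spectral_descriptors(power, freqs, (500, 2000))
        assert out[1] <= out[0]

    def test_silent_frame_sentinels(self):
        freqs = np.arange(0, 4001, 10.0)
        assert np.allclose(
            spectral_descriptors(np.zeros_like(freqs), freqs, (0, 4000)), 0.0)


class TestLpc:
    def test_recovers_known_ar2_pole(self):
        r0, theta = 0.95, np.pi / 4
        a = [1.0, -2 * r0 * np.cos(theta), r0**2]
        rng = np.random.default_rng(1)
        x = scipy.signal.lfilter([1.0], a, rng.standard_normal(8000))
        model = lpc_fit(x, 2)
        z = model.roots[np.imag(model.roots) > 0][0]
        assert abs(np.abs(z) - r0) / r0 < 0.01
        assert abs(np.angle(z) - theta) / theta < 0.01

    def test_white_noise_envelope_nearly_flat(self):
        rng = np.random.default_rng(2)
        model = lpc_fit(rng.standard_normal(4000), 12)
        env = model.envelope(np.linspace(0, RATE / 2, 200), RATE)
        assert env.max() / env.min() < 3.0

    def test_order_zero_is_trivial(self):
        model = lpc_fit(np.sin(np.arange(100)), 0)
        assert model.coefficients.tolist() == [1.0]
        env = model.envelope(np.array([100.0, 1000.0]), RATE)
        assert env[0] == env[1]

    def test_rejects_degenerate_frame(self):
        with pytest.raises(ValueError, match="degenerate"):
            lpc_fit(np.ones(100), 4)


class TestFormants:
    def test_pole_angle_maps_to_frequency(self):
        z = 0.9 * np.exp(1j * np.pi / 4)
        model = LpcModel(order=2, coefficients=np.real(np.poly([z, z.conj()])),
                         roots=np.array([z, z.conj()]))
        out = formants_from_lpc(model, 8000.0)
        assert out[0, 0] == pytest.approx(1000.0)
        assert out[0, 1] == 0.0 and out[1, 1] == 0.0  # zero-padded

    def test_bandwidth_vanishes_as_radius_approaches_one(self):
        def bw(r):
            z = r * np.exp(1j * np.pi / 3)
            model = LpcModel(2, np.real(np.poly([z, z.conj()])),
                             np.array([z, z.conj()]))
            return formants_from_lpc(model, 8000.0)[1, 0]

        assert bw(0.999) < bw(0.99) < bw(0.9)

    def test_output_sorted_by_frequency(self):
        z1 = 0.9 * np.exp(1j * 2.0)   # high frequency listed first
        z2 = 0.9 * np.exp(1j * 0.5)
        roots = np.array([z1, z1.conj(), z2, z2.conj()])
        model = LpcModel(4, np.real(np.poly(roots)), roots)
        out = formants_from_lpc(model, 8000.0)
        assert out[0, 0] < out[0, 1]


class TestPitchAndHarmonicity:
    def test_pulse_train_pitch(self):
        frame = np.zeros(4000)
        frame[::320] = 1.0  # 25 pulses/s at 8 kHz
        est = pitch_estimate(frame, RATE, (10.0, 100.0))
        assert est == pytest.approx(25.0, abs=RATE / 320 - RATE / 321)

    def test_pure_tone_pitch(self):
        tone = np.sin(2 * np.pi * 200 * np.arange(4000) / RATE)
        assert pitch_estimate(tone, RATE, (50.0, 1000.0)) == pytest.approx(
            200.0, abs=5.0)

    def test_white_noise_unvoiced(self):
        rng = np.random.default_rng(3)
        assert pitch_estimate(rng.standard_normal(4000), RATE,
                              (50.0, 1000.0)) == 0.0

    def test_periodic_signal_high_harmonicity(self):
        tone = np.sin(2 * np.pi * 200 * np.arange(8000) / RATE)
        ratio, ulh = harmonicity_descriptors(tone, RATE)
        assert ratio > 0.99
        assert ulh > 0

    def test_white_noise_low_harmonicity(self):
        rng = np.random.default_rng(4)
        ratio, _ = harmonicity_descriptors(rng.standard_normal(4000), RATE)
        assert ratio < 0.3

    def test_single_impulse_aperiodic(self):
        frame = np.zeros(2000)
        frame[100] = 1.0
        ratio, ulh = harmonicity_descriptors(frame, RATE)
        assert ratio == pytest.approx(0.0, abs=0.05)
        assert ulh == 0.0


class TestHarmonicDescriptors:
    def grid(self):
        return np.arange(0, 4001, 10.0)

    def test_single_harmonic_centroid_at_pitch(self):
        freqs = self.grid()
        power = np.zeros_like(freqs)
        power[freqs == 200.0] = 4.0
        centroid, _, spread, _ = harmonic_descriptors(power, freqs, 200.0)
        assert centroid == pytest.approx(200.0)
        assert spread == pytest.approx(0.0)

    def test_two_equal_harmonics_centroid(self):
        freqs = self.grid()
        power = np.zeros_like(freqs)
        power[freqs == 200.0] = 1.0
        power[freqs == 400.0] = 1.0
        centroid = harmonic_descriptors(power, freqs, 200.0)[0]
        assert centroid == pytest.approx(300.0)

    def test_identical_frames_zero_variation(self):
        freqs = self.grid()
        power = np.zeros_like(freqs)
        power[freqs == 200.0] = 1.0
        power[freqs == 400.0] = 0.5
        amps = np.array([1.0, np.sqrt(0.5)])
        variation = harmonic_descriptors(power, freqs, 200.0, amps)[3]
        assert variation == pytest.approx(0.0, abs=1e-9)

    def test_unvoiced_sentinels(self):
        freqs = self.grid()
        assert np.allclose(
            harmonic_descriptors(np.ones_like(freqs), freqs, 0.0), 0.0)


class TestFullVector:
    def test_vector_length_and_names(self):
        rng = np.random.default_rng(5)
        vec = mpeg7_features(rng.standard_normal(1000), None, RATE, (0, 4000))
        assert vec.shape == (18,)
        assert len(MPEG7_FEATURE_NAMES) == 18

    def test_pure_tone_frame(self):
        tone = np.sin(2 * np.pi * 500 * np.arange(2000) / RATE)
        vec = mpeg7_features(tone, None, RATE, (0, 4000))
        named = dict(zip(MPEG7_FEATURE_NAMES, vec))
        assert named["formant_freq_1_hz"] == pytest.approx(500.0, abs=50.0)
        assert named["spectrum_flatness"] < 0.1
        assert named["pitch_hz"] == pytest.approx(500.0, abs=10.0)

    def test_silent_frame_all_sentinels(self):
        vec = mpeg7_features(np.zeros(1000), None, RATE, (0, 4000))
        assert np.allclose(vec, 0.0)

    def test_scale_invariant_descriptors(self):
        rng = np.random.default_rng(6)
        frame = rng.standard_normal(2000) + np.sin(
            2 * np.pi * 300 * np.arange(2000) / RATE)
        a = mpeg7_features(frame, None, RATE, (0, 4000))
        b = mpeg7_features(10 * frame, None, RATE, (0, 4000))
        names = list(MPEG7_FEATURE_NAMES)
        for key in ("power_centroid_hz", "spectral_dispersion_hz",
                    "spectrum_flatness", "harmonicity_ratio"):
            i = names.index(key)
            assert b[i] == pytest.approx(a[i], rel=1e-6, abs=1e-9)
        # powers scale by the square of the amplitude factor
        assert b[0] == pytest.approx(100 * a[0], rel=1e-9)
        assert b[1] <= b[0] and a[1] <= a[0]
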