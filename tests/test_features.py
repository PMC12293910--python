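"""RMS envelope, scalar vibration features, and MFCC extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vibrouroflow import (MfccConfig, RmsEnvelope, VibrationRecord,
                          compute_mfcc, compute_rms_envelope,
                          extract_vibration_features)
from vibrouroflow.errors import (InvalidConfigError, NoSignalError,
                                 TooShortSignalError)

FS = 4000.0


def record(x):
    return VibrationRecord(fs=FS, samples=np.asarray(x, dtype=float))


class TestRmsEnvelope:
    def test_constant_signal(self):
        env = compute_rms_envelope(record(np.full(8000, 0.7)))
        assert np.allclose(env.values, 0.7)

    def test_zero_signal(self):
        env = compute_rms_envelope(record(np.zeros(8000)))
        assert np.all(env.values == 0)

    def test_sine_matches_closed_form(self):
        # >= 10 periods per 100 ms window -> RMS = 1/sqrt(2) within 1 %
        t = np.arange(40000) / FS
        env = compute_rms_envelope(record(np.sin(2 * np.pi * 200 * t)))
        assert np.allclose(env.values, 1 / np.sqrt(2), rtol=0.01)

    def test_too_short_record(self):
        with pytest.raises(TooShortSignalError):
            compute_rms_envelope(record(np.zeros(100)))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_sign_flip_invariance(self, seed):
        x = np.random.default_rng(seed).standard_normal(4000)
        a = compute_rms_envelope(record(x)).values
        b = compute_rms_envelope(record(-x)).values
        assert np.array_equal(a, b)

    def test_timestamps_are_window_centers(self):
        env = compute_rms_envelope(record(np.ones(8000)), window=0.1, hop=0.05)
        assert env.times[0] == pytest.approx(0.05)
        assert np.allclose(np.diff(env.times), 0.05)


class TestVibrationFeatures:
    def test_rectangular_envelope(self):
        env = RmsEnvelope(hop=0.05, window=0.1, values=np.full(201, 2.5))
        f = extract_vibration_features(env, onset_frac=0.05)
        assert f.mmax == 2.5
        assert f.signal_time == pytest.approx(200 * 0.05)
        assert f.time_to_mmax == 0.0
        # integral scalar = height x envelope extent
        assert f.rms_magnitude == pytest.approx(2.5 * 201 * 0.05)
        f_rms = extract_vibration_features(env, rms_stat="rms")
        assert f_rms.rms_magnitude == pytest.approx(2.5)

    def test_triangular_envelope_peak_time(self):
        vals = np.concatenate([np.linspace(0, 3, 101), np.linspace(3, 0, 101)[1:]])
        env = RmsEnvelope(hop=0.05, window=0.1, values=vals)
        f = extract_vibration_features(env)
        # onset sits a few threshold-crossing points after t=0, so the
        # measured peak delay is slightly under the 5 s ramp
        assert f.time_to_mmax == pytest.approx(5.0, abs=0.6)

    def test_tied_maxima_take_the_earlier(self):
        vals = np.zeros(100)
        vals[20:80] = 1.0
        vals[30] = vals[60] = 2.0
        env = RmsEnvelope(hop=0.05, window=0.1, values=vals)
        f = extract_vibration_features(env)
        assert f.time_to_mmax == pytest.approx((30 - 20) * 0.05)

    def test_all_zero_envelope(self):
        env = RmsEnvelope(hop=0.05, window=0.1, values=np.zeros(50))
        with pytest.raises(NoSignalError):
            extract_vibration_features(env)

    @pytest.mark.parametrize("gain", [0.1, 3.0, 40.0])
    def test_waveform_gain_covariance(self, gain):
        """Scaling the waveform by c scales amplitudes by exactly c and
        leaves the temporal features unchanged (relative threshold)."""
        rng = np.random.default_rng(3)
        x = np.zeros(40000)
        x[8000:32000] = rng.standard_normal(24000) * np.hanning(24000)
        f1 = extract_vibration_features(compute_rms_envelope(record(x)))
        f2 = extract_vibration_features(compute_rms_envelope(record(gain * x)))
        assert f2.mmax == pytest.approx(gain * f1.mmax, rel=1e-9)
        assert f2.rms_magnitude == pytest.approx(gain * f1.rms_magnitude, rel=1e-9)
        assert f2.signal_time == f1.signal_time
        assert f2.time_to_mmax == f1.time_to_mmax


class TestMfcc:
    def test_silence_maps_to_identical_floor_frames(self):
        spec = compute_mfcc(record(np.zeros(4000)))
        assert spec.coeffs.shape == (6400, 13)
        assert np.allclose(spec.coeffs, spec.coeffs[0])

    def test_tone_differs_from_noise(self):
        t = np.arange(4000) / FS
        tone = np.sin(2 * np.pi * 600 * t)
        noise = np.random.default_rng(0).standard_normal(4000) / np.sqrt(2)
        a = compute_mfcc(record(tone)).coeffs
        b = compute_mfcc(record(noise)).coeffs
        assert np.abs(a - b).mean() > 0

    def test_deterministic(self):
        x = np.random.default_rng(1).standard_normal(8000)
        a = compute_mfcc(record(x))
        b = compute_mfcc(record(x))
        assert np.array_equal(a.coeffs, b.coeffs)
        assert a.config_digest == b.config_digest

    def test_fixed_shape_across_durations(self):
        short = compute_mfcc(record(np.random.default_rng(2).standard_normal(4000)))
        long = compute_mfcc(record(np.random.default_rng(2).standard_normal(300000)))
        assert short.coeffs.shape == long.coeffs.shape == (6400, 13)

    def test_mel_edge_above_nyquist_rejected(self):
        with pytest.raises(InvalidConfigError):
            compute_mfcc(record(np.zeros(4000)), MfccConfig(fmax=3000.0))
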