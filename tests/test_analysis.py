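"""Propagation delay, spectrogram/band power and PLV estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slesim.analysis import (DEFAULT_BANDS, BandSpec, band_power_fractions,
                             dominant_frequency, plv, propagation_delay,
                             spectrogram)
from slesim.exceptions import (AnalysisError, ConfigurationError,
                               InsufficientDataError)

FS = 1000.0


def peaked_wave(t, freq=8.0):
    """Oscillation with one sharp positive peak per cycle."""
    return np.maximum(0.0, np.cos(2 * np.pi * freq * t)) ** 3


class TestPropagationDelay:
    def test_recovers_exact_lag(self):
        t = np.arange(4000) / FS
        lag = 8.5e-3
        ch = np.array([peaked_wave(t), peaked_wave(t - lag)])
        res = propagation_delay(ch, FS)
        assert res.mean_delay_ms == pytest.approx(8.5, abs=1.0)  # one sample

    def test_identical_channels_give_zero(self):
        t = np.arange(3000) / FS
        ch = np.tile(peaked_wave(t), (3, 1))
        assert propagation_delay(ch, FS).mean_delay_ms == 0.0

    def test_pair_delays_7_and_10_average_to_8_5(self):
        t = np.arange(4000) / FS
        ch = np.array([peaked_wave(t), peaked_wave(t - 7e-3),
                       peaked_wave(t - 17e-3)])
        res = propagation_delay(ch, FS)
        assert res.pair_delays_ms[(0, 1)] == pytest.approx(7.0, abs=1.0)
        assert res.pair_delays_ms[(1, 2)] == pytest.approx(10.0, abs=1.0)
        assert res.mean_delay_ms == pytest.approx(8.5, abs=1.0)

    @pytest.mark.parametrize("lag_ms", [2.0, 10.0, 25.0])
    def test_lags_up_to_25ms_recovered_noise_free(self, lag_ms):
        t = np.arange(5000) / FS
        ch = np.array([peaked_wave(t, 6.0), peaked_wave(t - lag_ms / 1e3, 6.0)])
        res = propagation_delay(ch, FS, max_lag_ms=30.0)
        assert res.mean_delay_ms == pytest.approx(lag_ms, abs=1.0)

    def test_lag_recovery_under_noise(self):
        rng = np.random.default_rng(0)
        t = np.arange(5000) / FS
        clean = peaked_wave(t)
        snr_amp = 10 ** (-10 / 20) * np.std(clean)  # SNR 10 dB
        ch = np.array([clean + snr_amp * rng.standard_normal(t.size),
                       peaked_wave(t - 8.5e-3)
                       + snr_amp * rng.standard_normal(t.size)])
        res = propagation_delay(ch, FS)
        assert res.mean_delay_ms == pytest.approx(8.5, abs=2.0)

    def test_too_few_peaks_raises(self):
        flat = np.zeros((2, 1000))
        with pytest.raises(InsufficientDataError):
            propagation_delay(flat, FS)

    def test_window_outside_signal_rejected(self):
        t = np.arange(1000) / FS
        ch = np.tile(peaked_wave(t), (2, 1))
        with pytest.raises(AnalysisError):
            propagation_delay(ch, FS, window=(500.0, 5000.0))


class TestSpectrogram:
    def test_pure_tone_peak_within_one_bin(self):
        t = np.arange(6000) / FS
        f, tt, sxx = spectrogram(np.sin(2 * np.pi * 10.0 * t), FS)
        # the 256-sample window's negative-frequency leakage biases the
        # interpolated peak by up to ~2 DFT bins at 10 Hz
        bin_hz = FS / 8192
        for frame in range(sxx.shape[1]):
            assert abs(f[np.argmax(sxx[:, frame])] - 10.0) <= 2 * bin_hz + 1e-9

    def test_silence_has_negligible_power(self):
        f, tt, sxx = spectrogram(np.zeros(2000), FS)
        assert sxx.max() < 1e-20

    def test_equal_tones_give_equal_ridges_within_1db(self):
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 6.0 * t) + np.sin(2 * np.pi * 20.0 * t)
        f, tt, sxx = spectrogram(x, FS)
        mean = sxx.mean(axis=1)
        p6 = mean[np.abs(f - 6.0).argmin()]
        p20 = mean[np.abs(f - 20.0).argmin()]
        assert abs(10 * np.log10(p6 / p20)) < 1.0

    def test_short_signal_rejected(self):
        with pytest.raises(AnalysisError):
            spectrogram(np.zeros(100), FS)


class TestBandPower:
    def test_pure_theta_tone_dominates(self):
        t = np.arange(6000) / FS
        # a 1024-sample window keeps the 6-Hz mainlobe inside the theta band
        fr = band_power_fractions(np.sin(2 * np.pi * 6.0 * t), FS,
                                  nperseg=1024)
        assert fr["theta"] > 0.95

    def test_fractions_sum_to_one_and_scale_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(4000)
        fr1 = band_power_fractions(x, FS)
        fr2 = band_power_fractions(100.0 * x, FS)
        assert sum(fr1.values()) == pytest.approx(1.0, abs=1e-9)
        for k in fr1:
            assert fr1[k] == pytest.approx(fr2[k], rel=1e-9)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            band_power_fractions(np.zeros(1000), 80.0)

    def test_band_spec_validation(self):
        with pytest.raises(ConfigurationError):
            BandSpec(bands=(("a", (4.0, 2.0)),))
        with pytest.raises(ConfigurationError):
            BandSpec(bands=(("a", (1.0, 5.0)), ("b", (4.0, 8.0))))


class TestDominantFrequency:
    def test_pure_tone(self):
        t = np.arange(4000) / FS
        f, conf = dominant_frequency(np.sin(2 * np.pi * 8.0 * t), FS)
        assert f == pytest.approx(8.0, abs=FS / 8192 + 1e-9)
        assert conf

    def test_tone_in_noise_snr_10db(self):
        rng = np.random.default_rng(2)
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 8.0 * t)
        x = x + 10 ** (-10 / 20) * np.std(x) * rng.standard_normal(x.size)
        f, conf = dominant_frequency(x, FS)
        assert f == pytest.approx(8.0, abs=FS / 8192 + 1e-9)

    def test_white_noise_flagged_low_confidence(self):
        rng = np.random.default_rng(3)
        f, conf = dominant_frequency(rng.standard_normal(4000), FS)
        assert not conf


class TestPLV:
    def test_identical_channels_give_unity(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(4000)
        ch = np.tile(x, (4, 1))
        res = plv(ch, "theta", FS)
        assert res.plv == pytest.approx(1.0, abs=1e-6)
        assert res.plv_instantaneous == pytest.approx(1.0, abs=1e-6)

    def test_fixed_phase_offsets_lock_each_pair(self):
        t = np.arange(4000) / FS
        ch = np.array([np.sin(2 * np.pi * 6.0 * t + np.deg2rad(p))
                       for p in (0.0, 10.0, 20.0, 30.0)])
        res = plv(ch, "theta", FS, window=(500.0, 3500.0))
        for pair_plv in res.per_pair.values():
            assert pair_plv == pytest.approx(1.0, abs=1e-3)

    def test_independent_noise_has_low_plv(self):
        rng = np.random.default_rng(5)
        ch = rng.standard_normal((4, 20000))
        res = plv(ch, "theta", FS)
        assert res.plv < 0.2

    def test_invariant_to_common_shift_and_scaling(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((4, 6000)).cumsum(axis=1)
        r1 = plv(x, "alpha", FS, window=(1000.0, 5000.0))
        shifted = np.roll(x, 250, axis=1) * 13.7
        r2 = plv(shifted, "alpha", FS, window=(1250.0, 5250.0))
        assert r1.plv == pytest.approx(r2.plv, abs=0.02)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            plv(np.zeros((2, 1000)), (400.0, 600.0), FS)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           band=st.sampled_from(DEFAULT_BANDS.names))
    def test_plv_always_in_unit_interval(self, seed, band):
        rng = np.random.default_rng(seed)
        ch = rng.standard_normal((3, 2000))
        res = plv(ch, band, FS)
        assert 0.0 <= res.plv <= 1.0
        assert 0.0 <= res.plv_instantaneous <= 1.0
        for v in res.per_pair.values():
            assert 0.0 <= v <= 1.0
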