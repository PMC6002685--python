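"""Spectral engine: transform correctness, detection, filters, tracking."""

import numpy as np
import pytest

from soaekit.spectral import (
    NoSOAEsError,
    Spectrum,
    analysis_window,
    baseline_spectrum,
    detect_soae_candidates,
    line_noise_filter,
    select_test_ear,
    stability_filter,
    stability_sd_from_levels,
    stft,
    track_peak,
)
from soaekit.synth import simulate_soae_waveform, OscillatorSpec
from soaekit.types import EarCanalRecording, SOAEPeak, STFTParams


def dft_oracle_frame(x, params, frame_index):
    """Single-frame reference transform: same window, same zero-padding."""
    w = analysis_window(params)
    seg = x[frame_index * params.hop:frame_index * params.hop + params.window]
    return np.abs(np.fft.rfft(seg * w, params.n_fft))


class TestSTFT:
    def test_matches_direct_dft_oracle(self, small_params, rng):
        x = rng.standard_normal(int(2.0 * small_params.sample_rate))
        rec = EarCanalRecording(x, small_params.sample_rate)
        gram = stft(rec, small_params)
        w = analysis_window(small_params)
        for i in [0, 3, gram.n_frames - 1]:
            oracle = 2.0 / w.sum() * dft_oracle_frame(x, small_params, i)
            got = 10.0 ** ((gram.levels[i] - rec.calibration_db) / 20.0)
            assert np.allclose(got, np.maximum(oracle, 1e-10), rtol=1e-6)

    def test_frame_count_and_times(self, small_params):
        n = int(3.0 * small_params.sample_rate)
        rec = EarCanalRecording(np.zeros(n), small_params.sample_rate)
        gram = stft(rec, small_params)
        expected = (n - small_params.window) // small_params.hop + 1
        assert gram.n_frames == expected
        # window-center convention
        assert gram.frame_times[0] == pytest.approx(
            small_params.window / 2 / small_params.sample_rate)
        assert np.allclose(np.diff(gram.frame_times), small_params.hop_s)

    def test_standard_framing_of_three_minutes(self):
        # 180 s at 44.1 kHz under the default frame/hop convention
        assert STFTParams().n_frames(7_938_000) == 1934

    def test_bin_spacing_is_two_hz_at_defaults(self):
        assert STFTParams().bin_hz == pytest.approx(2.0)

    def test_pure_tone_lands_in_expected_bin(self):
        params = STFTParams()
        t = np.arange(int(0.6 * params.sample_rate)) / params.sample_rate
        rec = EarCanalRecording(0.01 * np.sin(2 * np.pi * 2000 * t),
                                params.sample_rate)
        gram = stft(rec, params)
        assert np.argmax(gram.levels[0]) == 1000  # 2000 Hz / 2 Hz per bin

    def test_all_zero_input_is_finite(self, small_params):
        rec = EarCanalRecording(np.zeros(small_params.window + 1),
                                small_params.sample_rate)
        gram = stft(rec, small_params)
        assert np.all(np.isfinite(gram.levels))

    def test_too_short_recording_names_minimum(self, small_params):
        rec = EarCanalRecording(np.zeros(10), small_params.sample_rate)
        with pytest.raises(ValueError, match=str(small_params.window)):
            stft(rec, small_params)


class TestBaselineSpectrum:
    def test_single_oscillator_frequency_and_level(self, small_params):
        spec = OscillatorSpec(2000.0, -5.0)
        x = simulate_soae_waveform(spec, 20.0, small_params.sample_rate, seed=3)
        sp = baseline_spectrum(EarCanalRecording(x, small_params.sample_rate),
                               small_params)
        peak = np.argmax(sp.levels)
        assert abs(sp.frequencies[peak] - 2000.0) <= small_params.bin_hz
        assert sp.levels[peak] == pytest.approx(-5.0, abs=0.5)

    def test_two_oscillators_100_hz_apart_resolved(self, small_params, rng):
        x = sum(simulate_soae_waveform(OscillatorSpec(f, -5.0), 20.0,
                                       small_params.sample_rate, seed=s)
                for s, f in [(1, 2000.0), (2, 2100.0)])
        x = x + 1e-4 * rng.standard_normal(x.size)  # microphone noise floor
        sp = baseline_spectrum(EarCanalRecording(x, small_params.sample_rate),
                               small_params)
        peaks = detect_soae_candidates(sp, fmin=1500, fmax=2500)
        assert [round(p.frequency) for p in peaks] == [2000, 2100]

    def test_white_noise_yields_no_candidates(self, small_params, rng):
        x = 1e-4 * rng.standard_normal(int(20 * small_params.sample_rate))
        sp = baseline_spectrum(EarCanalRecording(x, small_params.sample_rate),
                               small_params)
        assert detect_soae_candidates(sp, fmin=1000, fmax=3500) == []


def flat_spectrum_with_peaks(peaks_hz_db, floor_db=-25.0, fmax=4000):
    freqs = np.arange(0.0, fmax, 2.0)
    levels = np.full(freqs.size, floor_db)
    for f, level in peaks_hz_db:
        levels[int(f // 2)] = level
    return Spectrum(freqs, levels)


class TestDetection:
    def test_single_peak_above_threshold(self):
        sp = flat_spectrum_with_peaks([(2000.0, -10.0)])  # 15 dB above floor
        got = detect_soae_candidates(sp, snr_threshold=10.0, fmin=1000,
                                     fmax=3500)
        assert [(p.frequency, p.baseline_level) for p in got] == [(2000.0, -10.0)]

    def test_flat_spectrum_empty(self):
        sp = flat_spectrum_with_peaks([])
        assert detect_soae_candidates(sp, fmin=1000, fmax=3500) == []

    def test_minimum_separation_keeps_higher(self):
        sp = flat_spectrum_with_peaks([(2000.0, -8.0), (2008.0, -5.0)])
        got = detect_soae_candidates(sp, fmin=1000, fmax=3500,
                                     min_separation_hz=10.0)
        assert [p.frequency for p in got] == [2008.0]

    def test_out_of_band_peaks_ignored(self):
        sp = flat_spectrum_with_peaks([(500.0, -5.0), (2000.0, -5.0)])
        got = detect_soae_candidates(sp, fmin=1000, fmax=3500)
        assert [p.frequency for p in got] == [2000.0]


class TestStabilityFilter:
    def test_sample_sd_of_alternating_levels(self):
        # (0, 12, 0, 12) has sample SD sqrt(48) ~ 6.93 -> removed
        assert stability_sd_from_levels([0, 12, 0, 12]) == pytest.approx(
            np.sqrt(48.0))
        assert stability_sd_from_levels([-5, -5, -5, -5]) == 0.0

    def test_threshold_is_strictly_greater_than(self):
        sd = 6.0
        assert not sd > 6.0  # the rule that keeps an SD of exactly 6 dB

    def test_steady_oscillator_kept_variable_removed(self, small_params):
        fs = small_params.sample_rate
        seg = int(1.0 * fs)
        steady = simulate_soae_waveform(OscillatorSpec(2000.0, -5.0), 4.0, fs, 5)
        # amplitude steps 0/+16/0/+16 dB across four 1-s segments
        gains = np.repeat(10.0 ** (np.array([0, 16, 0, 16]) / 20.0), seg)
        variable = simulate_soae_waveform(OscillatorSpec(1000.0, -5.0), 4.0,
                                          fs, 6) * gains
        rec = EarCanalRecording(steady + variable, fs)
        peaks = [SOAEPeak(1000.0, -5.0), SOAEPeak(2000.0, -5.0)]
        out = stability_filter(rec, peaks, small_params, segment_s=1.0)
        by_freq = {p.frequency: p for p in out}
        assert by_freq[2000.0].excluded_by == "none"
        assert by_freq[2000.0].stability_sd < 1.0
        assert by_freq[1000.0].excluded_by == "stability"
        assert by_freq[1000.0].stability_sd > 6.0

    def test_short_baseline_rejected(self, small_params):
        rec = EarCanalRecording(np.zeros(int(60 * small_params.sample_rate)),
                                small_params.sample_rate)
        with pytest.raises(ValueError, match="120"):
            stability_filter(rec, [], small_params)


class TestLineNoiseFilter:
    @pytest.mark.parametrize("freq, excluded", [
        (1080.0, True),    # 18 x 60 exactly
        (1068.0, False),   # 12 Hz from the nearest multiple
        (2995.0, True),    # exactly 5 Hz away: inclusive boundary
        (2994.0, False),   # 6 Hz from 3,000
        (3004.0, True),
    ])
    def test_multiples_of_sixty(self, freq, excluded):
        out = line_noise_filter([SOAEPeak(freq, -5.0)])
        assert (out[0].excluded_by == "line_noise") is excluded

    def test_filters_only_touch_flags(self):
        peaks = [SOAEPeak(1080.0, -5.0), SOAEPeak(2000.0, -3.0)]
        out = line_noise_filter(peaks)
        assert [(p.frequency, p.baseline_level) for p in out] \
            == [(1080.0, -5.0), (2000.0, -3.0)]

    def test_commutes_with_stability_flagging(self, small_params):
        fs = small_params.sample_rate
        x = simulate_soae_waveform(OscillatorSpec(1080.0, -5.0), 4.0, fs, 7)
        rec = EarCanalRecording(x, fs)
        peaks = [SOAEPeak(1080.0, -5.0)]
        a = line_noise_filter(stability_filter(rec, peaks, small_params,
                                               segment_s=1.0))
        b = stability_filter(rec, line_noise_filter(peaks), small_params,
                             segment_s=1.0)
        assert [p.excluded_by for p in a] == [p.excluded_by for p in b]
        assert [p.surviving for p in a] == [p.surviving for p in b]


class TestEarSelection:
    def test_more_peaks_wins(self):
        left = [SOAEPeak(2000.0, -5), SOAEPeak(3000.0, -5), SOAEPeak(4000.0, -5)]
        right = [SOAEPeak(2500.0, -5)]
        assert select_test_ear(left, right) == "left"

    def test_out_of_range_peaks_do_not_count(self):
        left = [SOAEPeak(2000.0, -5)]
        right = [SOAEPeak(900.0, -5), SOAEPeak(10500.0, -5)]
        assert select_test_ear(left, right) == "left"

    def test_tie_goes_right(self):
        left = [SOAEPeak(2000.0, -5), SOAEPeak(3000.0, -5)]
        right = [SOAEPeak(2500.0, -5), SOAEPeak(3500.0, -5)]
        assert select_test_ear(left, right) == "right"

    def test_excluded_peaks_do_not_count(self):
        left = [SOAEPeak(2000.0, -5), SOAEPeak(3000.0, -5),
                SOAEPeak(4000.0, -5)]
        right = [SOAEPeak(2500.0, -5, excluded_by="line_noise"),
                 SOAEPeak(3500.0, -5), SOAEPeak(4500.0, -5),
                 SOAEPeak(5500.0, -5, excluded_by="stability")]
        # 3 surviving vs 2: left wins only because exclusions do not count
        assert select_test_ear(left, right) == "left"

    def test_no_soaes_anywhere_raises(self):
        with pytest.raises(NoSOAEsError):
            select_test_ear([], [SOAEPeak(900.0, -5)])


class TestTrackPeak:
    def make_levels(self, freqs, peak_at=None, peak_level=-5.0):
        levels = -30.0 - 0.001 * freqs  # gently sloping floor
        if peak_at is not None:
            i = int(peak_at)
            levels[i - 1:i + 2] = [peak_level - 3, peak_level, peak_level - 3]
        return levels

    def test_finds_offset_peak(self):
        freqs = np.arange(0.0, 4000.0)
        levels = self.make_levels(freqs, peak_at=2010)
        got = track_peak(freqs, levels, 2000.0, halfwidth_hz=25.0)
        assert got == (2010.0, -5.0)

    def test_monotonic_window_is_missing(self):
        freqs = np.arange(0.0, 4000.0)
        levels = 0.01 * freqs  # strictly increasing
        assert track_peak(freqs, levels, 2000.0) is None

    def test_window_boundary_inclusive(self):
        freqs = np.arange(0.0, 4000.0)
        levels = self.make_levels(freqs, peak_at=2025)
        got = track_peak(freqs, levels, 2000.0, halfwidth_hz=25.0)
        assert got is not None and got.frequency == 2025.0

    def test_just_outside_window_excluded(self):
        freqs = np.arange(0.0, 4000.0)
        levels = self.make_levels(freqs, peak_at=2026)
        assert track_peak(freqs, levels, 2000.0, halfwidth_hz=25.0) is None

    def test_window_beyond_spectrum_raises(self):
        freqs = np.arange(0.0, 100.0)
        with pytest.raises(ValueError, match="window"):
            track_peak(freqs, np.zeros(100), 90.0, halfwidth_hz=25.0)
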