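"""Spectral analysis of ear-canal recordings.

Implements the short-time Fourier transform used throughout the pipeline,
baseline SOAE identification in a 3-min silent recording, the two exclusion
filters (level stability across four 30-s baseline segments; proximity to a
60 Hz line-noise harmonic), test-ear selection, and per-frame peak tracking
within +/-25 Hz of a baseline emission.

Conventions (all configurable):
- Frame timestamps use the window-center convention.
- Bin magnitudes are scaled by 2 / sum(window), so a sinusoid at a bin
  center reads its waveform amplitude; dB levels add the recording's
  calibration constant.
- The baseline spectrum averages frames in the power domain, then converts
  to dB.
- The 5 Hz line-noise tolerance and the 25 Hz tracking window are inclusive;
  the 6 dB stability threshold is exclusive (strictly greater than).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import scipy.fft
from scipy.ndimage import median_filter
from scipy.signal import find_peaks, get_window

from .types import DB_FLOOR, EarCanalRecording, SOAEPeak, Spectrogram, STFTParams

__all__ = [
    "NoSOAEsError",
    "Spectrum",
    "TrackedPeak",
    "analysis_window",
    "stft",
    "average_spectrum",
    "baseline_spectrum",
    "baseline_spectra_with_segments",
    "smoothed_noise_floor",
    "detect_soae_candidates",
    "stability_sd_from_levels",
    "stability_filter",
    "line_noise_filter",
    "select_test_ear",
    "track_peak",
]

_FRAME_CHUNK = 256  # frames per FFT batch; caps transient memory


class NoSOAEsError(ValueError):
    """Raised when neither ear has a surviving emission (subject excluded)."""


class TrackedPeak(NamedTuple):
    frequency: float
    level: float


@dataclass
class Spectrum:
    """A single averaged spectrum: frequencies (Hz) and levels (dB)."""

    frequencies: np.ndarray
    levels: np.ndarray

    @property
    def bin_hz(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def analysis_window(params: STFTParams) -> np.ndarray:
    """The periodic Hamming analysis window for the given parameters."""
    return get_window("hamming", params.window, fftbins=True)


def _amp_floor() -> float:
    return 10.0 ** (DB_FLOOR / 20.0)


def stft(recording: EarCanalRecording, params: STFTParams | None = None,
         dtype=np.float32) -> Spectrogram:
    """Short-time Fourier transform with calibrated dB magnitudes.

    Frames of ``params.window`` samples advance by ``params.hop``, are
    Hamming-windowed and zero-padded to ``params.n_fft``. Frame count is
    ``floor((N - window) / hop) + 1``; no boundary padding is applied.
    Levels are stored as ``dtype`` (float32 by default, which keeps
    3-minute spectrograms affordable; pass float64 for full precision).

    Raises
    ------
    ValueError
        If the recording is shorter than one analysis window.
    """
    params = params or STFTParams(sample_rate=recording.sample_rate)
    x = recording.samples
    n_frames = params.n_frames(x.size)  # raises with the required minimum
    win = analysis_window(params)
    scale = 2.0 / win.sum()
    n_bins = params.n_fft // 2 + 1
    levels = np.empty((n_frames, n_bins), dtype=dtype)
    offsets = np.arange(params.window)
    floor = _amp_floor()
    for i0 in range(0, n_frames, _FRAME_CHUNK):
        i1 = min(i0 + _FRAME_CHUNK, n_frames)
        starts = (np.arange(i0, i1) * params.hop)[:, None]
        frames = x[starts + offsets] * win
        amp = scale * np.abs(scipy.fft.rfft(frames, n=params.n_fft, axis=1))
        np.maximum(amp, floor, out=amp)
        levels[i0:i1] = 20.0 * np.log10(amp) + recording.calibration_db
    frame_times = (np.arange(n_frames) * params.hop + params.window / 2.0) / params.sample_rate
    frequencies = np.arange(n_bins) * params.bin_hz
    return Spectrogram(frame_times, frequencies, levels, params)


def average_spectrum(gram: Spectrogram,
                     frame_mask: np.ndarray | None = None) -> Spectrum:
    """Power-domain average of spectrogram frames, converted back to dB."""
    levels = gram.levels if frame_mask is None else gram.levels[frame_mask]
    power = np.mean(10.0 ** (levels.astype(np.float64) / 10.0), axis=0)
    out = 10.0 * np.log10(np.maximum(power, 10.0 ** (DB_FLOOR / 10.0)))
    return Spectrum(gram.frequencies, out)


def baseline_spectrum(
    recording: EarCanalRecording, params: STFTParams | None = None
) -> Spectrum:
    """Frame-averaged spectrum of a silent baseline recording.

    Frames are averaged in the power domain and the mean converted to dB,
    which is unbiased for stationary signals.
    """
    spectrum, _ = baseline_spectra_with_segments(recording, params,
                                                 n_segments=0)
    return spectrum


def baseline_spectra_with_segments(
    recording: EarCanalRecording,
    params: STFTParams | None = None,
    segment_s: float = 30.0,
    n_segments: int = 4,
) -> tuple[Spectrum, list[Spectrum]]:
    """Full-baseline average spectrum plus per-segment averages, one pass.

    Segment k averages (in power) the frames whose center time falls in
    ``[k * segment_s, (k+1) * segment_s)``. Avoids materializing per-frame
    dB levels, which matters on 3-minute baselines.
    """
    params = params or STFTParams(sample_rate=recording.sample_rate)
    x = recording.samples
    n_frames = params.n_frames(x.size)
    win = analysis_window(params)
    scale = 2.0 / win.sum()
    n_bins = params.n_fft // 2 + 1
    total = np.zeros(n_bins)
    seg_sums = np.zeros((n_segments, n_bins)) if n_segments else None
    seg_counts = np.zeros(n_segments, dtype=int) if n_segments else None
    offsets = np.arange(params.window)
    centers = (np.arange(n_frames) * params.hop + params.window / 2.0) \
        / params.sample_rate
    seg_of = (centers // segment_s).astype(int) if n_segments else None
    for i0 in range(0, n_frames, _FRAME_CHUNK):
        i1 = min(i0 + _FRAME_CHUNK, n_frames)
        starts = (np.arange(i0, i1) * params.hop)[:, None]
        frames = x[starts + offsets] * win
        power = np.abs(scipy.fft.rfft(frames, n=params.n_fft, axis=1)) ** 2
        total += power.sum(axis=0)
        if n_segments:
            for k in np.unique(seg_of[i0:i1]):
                if 0 <= k < n_segments:
                    rows = power[seg_of[i0:i1] == k]
                    seg_sums[k] += rows.sum(axis=0)
                    seg_counts[k] += rows.shape[0]
    cal = recording.calibration_db
    floor = 10.0 ** (DB_FLOOR / 10.0)

    def to_spectrum(mean_power: np.ndarray) -> Spectrum:
        levels = 10.0 * np.log10(np.maximum(scale ** 2 * mean_power, floor)) + cal
        return Spectrum(np.arange(n_bins) * params.bin_hz, levels)

    segments = []
    if n_segments:
        for k in range(n_segments):
            if seg_counts[k] == 0:
                raise ValueError(
                    f"baseline segment {k} ([{k * segment_s:.0f}, "
                    f"{(k + 1) * segment_s:.0f}) s) contains no frames"
                )
            segments.append(to_spectrum(seg_sums[k] / seg_counts[k]))
    return to_spectrum(total / n_frames), segments


def smoothed_noise_floor(spectrum: Spectrum, bandwidth_hz: float = 200.0) -> np.ndarray:
    """Median-smoothed noise-floor estimate of a spectrum (dB per bin)."""
    n_bins = max(3, int(round(bandwidth_hz / spectrum.bin_hz)) | 1)  # odd
    return median_filter(spectrum.levels, size=n_bins, mode="nearest")


def detect_soae_candidates(
    spectrum: Spectrum,
    snr_threshold: float = 6.0,
    fmin: float = 1000.0,
    fmax: float = 10000.0,
    floor_bandwidth_hz: float = 200.0,
    min_separation_hz: float = 10.0,
) -> list[SOAEPeak]:
    """Pick SOAE candidates: local maxima rising above the smoothed floor.

    A candidate is a local maximum within [fmin, fmax] whose level exceeds
    the median-smoothed noise floor by at least ``snr_threshold`` dB. When
    two candidates lie within ``min_separation_hz`` of each other only the
    higher is retained. Returned sorted by frequency; may be empty.
    """
    if not fmin < fmax:
        raise ValueError(f"fmin ({fmin}) must be < fmax ({fmax})")
    floor = smoothed_noise_floor(spectrum, floor_bandwidth_hz)
    idx, _ = find_peaks(spectrum.levels)
    f = spectrum.frequencies[idx]
    keep = (f >= fmin) & (f <= fmax) & (spectrum.levels[idx] >= floor[idx] + snr_threshold)
    idx = idx[keep]
    # minimum-separation rule: greedily keep the higher peak
    order = idx[np.argsort(spectrum.levels[idx])[::-1]]
    kept: list[int] = []
    for i in order:
        if all(abs(spectrum.frequencies[i] - spectrum.frequencies[j]) > min_separation_hz
               for j in kept):
            kept.append(i)
    kept.sort()
    return [
        SOAEPeak(frequency=float(spectrum.frequencies[i]),
                 baseline_level=float(spectrum.levels[i]))
        for i in kept
    ]


def stability_sd_from_levels(segment_levels: Sequence[float]) -> float:
    """Sample SD (n-1 denominator) of per-segment peak levels, in dB."""
    levels = np.asarray(segment_levels, dtype=float)
    if levels.size < 2:
        raise ValueError("stability SD needs at least two segment levels")
    return float(np.std(levels, ddof=1))


def _window_max_level(spectrum: Spectrum, frequency: float, halfwidth: float) -> float:
    mask = (spectrum.frequencies >= frequency - halfwidth - 1e-9) & (
        spectrum.frequencies <= frequency + halfwidth + 1e-9
    )
    return float(np.max(spectrum.levels[mask]))


def stability_filter(
    recording: EarCanalRecording,
    peaks: Sequence[SOAEPeak],
    params: STFTParams | None = None,
    threshold_db: float = 6.0,
    segment_s: float = 30.0,
    n_segments: int = 4,
    halfwidth_hz: float = 25.0,
    segment_spectra: list[Spectrum] | None = None,
) -> list[SOAEPeak]:
    """Flag emissions with highly variable levels across baseline segments.

    Each peak's level is measured in the first ``n_segments`` non-overlapping
    ``segment_s``-second segments of the baseline (the maximum level within
    +/-``halfwidth_hz`` of the peak, from each segment's averaged spectrum).
    Peaks whose sample SD is strictly greater than ``threshold_db`` (6 dB by
    default) are marked excluded. Frequencies and levels are never modified.

    Precomputed per-segment spectra (e.g. from
    :func:`baseline_spectra_with_segments`) may be passed to avoid
    re-transforming the baseline.
    """
    params = params or STFTParams(sample_rate=recording.sample_rate)
    needed = n_segments * segment_s
    if recording.duration_s + 1e-9 < needed:
        raise ValueError(
            f"stability filter needs a baseline of at least {needed:.0f} s; "
            f"got {recording.duration_s:.1f} s"
        )
    if segment_spectra is None:
        _, segment_spectra = baseline_spectra_with_segments(
            recording, params, segment_s, n_segments)
    elif len(segment_spectra) != n_segments:
        raise ValueError(
            f"expected {n_segments} segment spectra, got {len(segment_spectra)}")
    out = []
    for peak in peaks:
        seg_levels = [_window_max_level(s, peak.frequency, halfwidth_hz)
                      for s in segment_spectra]
        sd = stability_sd_from_levels(seg_levels)
        new = replace(peak, stability_sd=sd)
        if sd > threshold_db:
            new.excluded_by = "stability"
        out.append(new)
    return out


def line_noise_filter(
    peaks: Sequence[SOAEPeak],
    tolerance_hz: float = 5.0,
    fundamental_hz: float = 60.0,
) -> list[SOAEPeak]:
    """Flag emissions within ``tolerance_hz`` (inclusive) of a line harmonic.

    A peak at frequency f is excluded when ``|f - k * fundamental| <=
    tolerance`` for some positive integer k. Already-excluded peaks keep
    their earlier flag (the two filters commute on the surviving set).
    """
    if tolerance_hz < 0:
        raise ValueError("tolerance must be >= 0")
    out = []
    for peak in peaks:
        k = max(1, round(peak.frequency / fundamental_hz))
        dist = abs(peak.frequency - k * fundamental_hz)
        new = replace(peak)
        if dist <= tolerance_hz + 1e-9 and new.excluded_by == "none":
            new.excluded_by = "line_noise"
        out.append(new)
    return out


def select_test_ear(
    left_peaks: Sequence[SOAEPeak],
    right_peaks: Sequence[SOAEPeak],
    fmin: float = 1000.0,
    fmax: float = 10000.0,
) -> str:
    """Choose the ear with more surviving emissions in [fmin, fmax] Hz.

    Ties go to the right ear. Raises :class:`NoSOAEsError` when neither ear
    has a surviving in-range emission, mirroring the exclusion of subjects
    without SOAEs.
    """
    def tally(peaks: Sequence[SOAEPeak]) -> int:
        return sum(1 for p in peaks
                   if p.surviving and fmin <= p.frequency <= fmax)

    n_left, n_right = tally(left_peaks), tally(right_peaks)
    if n_left == 0 and n_right == 0:
        raise NoSOAEsError("no surviving SOAEs in either ear; subject excluded")
    return "left" if n_left > n_right else "right"


def track_peak(
    frequencies: np.ndarray,
    frame_levels: np.ndarray,
    baseline_frequency: float,
    halfwidth_hz: float = 25.0,
) -> TrackedPeak | None:
    """Locate the local peak within +/-``halfwidth_hz`` of a baseline SOAE.

    Returns the highest local maximum (a bin above its left neighbor and at
    least its right neighbor) whose frequency lies in the inclusive window,
    or ``None`` when no local maximum exists there (e.g. the spectrum is
    strictly monotonic across the window).
    """
    lo = baseline_frequency - halfwidth_hz
    hi = baseline_frequency + halfwidth_hz
    if lo < frequencies[0] or hi > frequencies[-1]:
        raise ValueError(
            f"tracking window [{lo:.1f}, {hi:.1f}] Hz extends beyond the "
            "spectrum range"
        )
    mask = (frequencies >= lo - 1e-9) & (frequencies <= hi + 1e-9)
    idx = np.flatnonzero(mask)
    # local-maximum test needs both neighbors; window interiority guarantees
    # they exist except at array edges
    idx = idx[(idx > 0) & (idx < frequencies.size - 1)]
    if idx.size == 0:
        return None
    is_max = (frame_levels[idx] > frame_levels[idx - 1]) & (
        frame_levels[idx] >= frame_levels[idx + 1]
    )
    idx = idx[is_max]
    if idx.size == 0:
        return None
    best = idx[np.argmax(frame_levels[idx])]
    return TrackedPeak(float(frequencies[best]), float(frame_levels[best]))
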