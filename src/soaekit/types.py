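"""Core data containers shared across the pipeline stages.

Levels throughout the package are expressed in dB SPL under a dataset-wide
calibration convention: a full-scale (amplitude 1.0) sinusoid, analyzed at a
frequency-bin center with the standard analysis parameters, reads
``calibration_db`` dB SPL at its peak bin. Synthetic datasets store the
constant in their ground-truth sidecar; any consistent value is acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Peak spectral level (dB SPL) of a full-scale sinusoid. See module docstring.
DEFAULT_CALIBRATION_DB = 90.0

#: Magnitudes below this dB level are clipped before taking logs.
DB_FLOOR = -200.0


@dataclass(frozen=True)
class STFTParams:
    """Short-time Fourier transform parameters.

    Defaults follow the analysis convention used for ear-canal SOAE
    recordings: 22,050-point transform of Hamming-windowed 16,384-sample
    frames advancing by 4,096 samples at 44.1 kHz, i.e. a 2 Hz bin spacing
    and a ~92.9 ms hop.
    """

    n_fft: int = 22050
    window: int = 16384
    hop: int = 4096
    sample_rate: float = 44100.0

    def __post_init__(self) -> None:
        if self.window > self.n_fft:
            raise ValueError(
                f"window ({self.window}) must be <= n_fft ({self.n_fft}); "
                "frames are zero-padded to n_fft"
            )
        if self.hop > self.window:
            raise ValueError(f"hop ({self.hop}) must be <= window ({self.window})")
        if min(self.n_fft, self.window, self.hop) <= 0 or self.sample_rate <= 0:
            raise ValueError("STFT parameters must be positive")

    @property
    def bin_hz(self) -> float:
        """Frequency-bin spacing in Hz (= sample_rate / n_fft)."""
        return self.sample_rate / self.n_fft

    @property
    def hop_s(self) -> float:
        return self.hop / self.sample_rate

    @property
    def window_s(self) -> float:
        return self.window / self.sample_rate

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.window:
            raise ValueError(
                f"recording of {n_samples} samples is shorter than one analysis "
                f"window ({self.window} samples)"
            )
        return (n_samples - self.window) // self.hop + 1


@dataclass
class EarCanalRecording:
    """A mono ear-canal microphone recording with its calibration constant."""

    samples: np.ndarray
    sample_rate: float
    ear: str = "unknown"  # "left" | "right" | "unknown"
    calibration_db: float = DEFAULT_CALIBRATION_DB

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("recording must be single-channel (1-D)")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class Spectrogram:
    """STFT output: per-frame levels in calibrated dB.

    ``frame_times`` follow the window-center convention; ``levels`` has shape
    (n_frames, n_bins).
    """

    frame_times: np.ndarray
    frequencies: np.ndarray
    levels: np.ndarray
    params: STFTParams

    @property
    def n_frames(self) -> int:
        return self.levels.shape[0]


@dataclass
class SOAEPeak:
    """A detected spontaneous emission and its filter status.

    ``excluded_by`` is one of ``"none"``, ``"stability"``, ``"line_noise"``.
    The two filters only set this flag; frequency and level are never touched.
    """

    frequency: float
    baseline_level: float
    stability_sd: float = float("nan")
    excluded_by: str = "none"

    @property
    def surviving(self) -> bool:
        return self.excluded_by == "none"


@dataclass(frozen=True)
class TrialEvent:
    """One speech-perception trial: a video/image lead-in followed by a syllable.

    The speech sound starts ``speech_onset_s - trial_onset_s`` (1.5 s by
    design) after the trial onset.
    """

    subject_id: str
    trial_index: int
    block: int
    trial_onset_s: float
    speech_onset_s: float
    syllable: str = "ba"
    response: str = ""


@dataclass
class SubjectRecord:
    """Subject metadata: language group, covariates, and raw task scores."""

    subject_id: str
    group: str  # "mono" | "early_bi" | "late_bi"
    english_aoa: float
    english_prof: float
    korean_prof: float
    vocabulary: float
    flanker: float
    working_memory: float
    card_sort: float
    pattern: float
    control_composite: float = field(default=float("nan"))
    working_memory_composite: float = field(default=float("nan"))

    @property
    def is_bilingual(self) -> bool:
        return self.group in ("early_bi", "late_bi")


GROUPS = ("mono", "early_bi", "late_bi")
BILINGUAL_GROUPS = ("early_bi", "late_bi")
TASK_COLUMNS = ("vocabulary", "flanker", "working_memory", "card_sort", "pattern")
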