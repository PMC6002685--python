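"""Trial-locked suppression measurement.

For every (trial x surviving SOAE) pair, the emission's tracked-peak level is
averaged over two 500-ms windows — the pre-trial baseline window ending at
trial onset, and the stimulus window starting at speech onset — and the
suppression observation is their difference in dB (stimulus minus baseline).
More suppression means a more negative delta.

Windows are half-open ``[t_start, t_start + duration)`` and include the
frames whose center time falls inside; frames without a trackable peak are
dropped, and a window with fewer than ``min_frames`` usable frames yields a
flagged missing measurement rather than a number.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .spectral import track_peak
from .types import SOAEPeak, Spectrogram, TrialEvent

__all__ = [
    "MEASUREMENT_COLUMNS",
    "WindowLevel",
    "window_average_level",
    "trial_delta",
    "measure_all",
]

MEASUREMENT_COLUMNS = [
    "subject_id",
    "trial_index",
    "soae_frequency_hz",
    "baseline_level_db",
    "stimulus_level_db",
    "delta_db",
    "n_frames_baseline",
    "n_frames_stimulus",
    "missing_reason",
]

DEFAULT_WINDOW_S = 0.5


class WindowLevel:
    """Mean tracked-peak level over one window, or the reason it is missing."""

    __slots__ = ("level", "n_frames", "missing_reason")

    def __init__(self, level: float, n_frames: int, missing_reason: str = ""):
        self.level = level
        self.n_frames = n_frames
        self.missing_reason = missing_reason

    @property
    def ok(self) -> bool:
        return not self.missing_reason


def window_average_level(
    gram: Spectrogram,
    soae: SOAEPeak,
    t_start: float,
    duration: float = DEFAULT_WINDOW_S,
    halfwidth_hz: float = 25.0,
    min_frames: int = 3,
) -> WindowLevel:
    """Average the tracked-peak level over ``[t_start, t_start + duration)``.

    The mean is taken in the dB domain over the frames whose center lies in
    the window and for which a local peak exists within +/-``halfwidth_hz``
    of the emission's baseline frequency.
    """
    if t_start + duration <= gram.frame_times[0] or t_start >= gram.frame_times[-1]:
        raise ValueError(
            f"window [{t_start:.3f}, {t_start + duration:.3f}) s lies outside "
            f"the analyzed span [{gram.frame_times[0]:.3f}, "
            f"{gram.frame_times[-1]:.3f}] s"
        )
    in_window = np.flatnonzero(
        (gram.frame_times >= t_start) & (gram.frame_times < t_start + duration)
    )
    levels = []
    for i in in_window:
        tracked = track_peak(gram.frequencies, gram.levels[i], soae.frequency,
                             halfwidth_hz)
        if tracked is not None:
            levels.append(tracked.level)
    if len(levels) < min_frames:
        return WindowLevel(
            float("nan"), len(levels),
            f"only {len(levels)} usable frames (minimum {min_frames})",
        )
    return WindowLevel(float(np.mean(levels)), len(levels))


def trial_delta(
    gram: Spectrogram,
    soae: SOAEPeak,
    event: TrialEvent,
    window_s: float = DEFAULT_WINDOW_S,
    halfwidth_hz: float = 25.0,
    min_frames: int = 3,
) -> dict:
    """One (trial x SOAE) suppression observation as a table row.

    ``delta_db = stimulus_level_db - baseline_level_db`` exactly; either
    window failing leaves the row flagged with a machine-readable reason.
    """
    def safe(t_start: float) -> WindowLevel:
        try:
            return window_average_level(gram, soae, t_start, window_s,
                                        halfwidth_hz, min_frames)
        except ValueError as exc:  # window beyond the analyzed span
            return WindowLevel(float("nan"), 0, str(exc))

    base = safe(event.trial_onset_s - window_s)
    stim = safe(event.speech_onset_s)
    reasons = []
    if not base.ok:
        reasons.append(f"baseline window: {base.missing_reason}")
    if not stim.ok:
        reasons.append(f"stimulus window: {stim.missing_reason}")
    delta = stim.level - base.level if not reasons else float("nan")
    return {
        "subject_id": event.subject_id,
        "trial_index": event.trial_index,
        "soae_frequency_hz": soae.frequency,
        "baseline_level_db": base.level,
        "stimulus_level_db": stim.level,
        "delta_db": delta,
        "n_frames_baseline": base.n_frames,
        "n_frames_stimulus": stim.n_frames,
        "missing_reason": "; ".join(reasons),
    }


def measure_all(
    gram: Spectrogram,
    events: Sequence[TrialEvent],
    soaes: Sequence[SOAEPeak],
    window_s: float = DEFAULT_WINDOW_S,
    halfwidth_hz: float = 25.0,
    min_frames: int = 3,
) -> pd.DataFrame:
    """Suppression measurements for every trial and surviving SOAE.

    Returns one row per (trial x surviving SOAE); excluded emissions are
    skipped entirely. An empty frame (with a warning) results when no
    emission survives.
    """
    surviving = [p for p in soaes if p.surviving]
    if not surviving:
        import warnings

        warnings.warn("no surviving SOAEs; measurement table is empty",
                      stacklevel=2)
    rows = [
        trial_delta(gram, soae, event, window_s, halfwidth_hz, min_frames)
        for event in events
        for soae in surviving
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
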