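"""Delimited-table I/O with schema checks and faithful round-trips."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from pandas.errors import ParserError
from scipy.io import wavfile

from .suppression import MEASUREMENT_COLUMNS
from .types import EarCanalRecording, TrialEvent

__all__ = [
    "EVENTS_COLUMNS",
    "METADATA_COLUMNS",
    "PEAKS_COLUMNS",
    "MEASUREMENT_COLUMNS",
    "read_table",
    "read_events",
    "events_to_frame",
    "read_wav",
]

EVENTS_COLUMNS = ["subject_id", "trial_index", "block", "trial_onset_s",
                  "speech_onset_s", "syllable", "response"]
METADATA_COLUMNS = ["subject_id", "group", "english_aoa", "english_prof",
                    "korean_prof", "vocabulary", "flanker", "working_memory",
                    "card_sort", "pattern"]
PEAKS_COLUMNS = ["subject_id", "ear", "frequency_hz", "baseline_level_db",
                 "stability_sd_db", "excluded_by"]


def read_table(path: str | Path, required_columns: list[str]) -> pd.DataFrame:
    """Read a CSV table, insisting on the required columns.

    Malformed rows are reported with their line number; a header-only file
    parses to an empty frame without error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_events(path: str | Path) -> list[TrialEvent]:
    df = read_table(path, EVENTS_COLUMNS)
    return [
        TrialEvent(
            subject_id=str(r.subject_id), trial_index=int(r.trial_index),
            block=int(r.block), trial_onset_s=float(r.trial_onset_s),
            speech_onset_s=float(r.speech_onset_s),
            syllable=str(r.syllable), response=str(r.response),
        )
        for r in df.itertuples()
    ]


def events_to_frame(events: list[TrialEvent]) -> pd.DataFrame:
    from dataclasses import asdict

    return pd.DataFrame([asdict(e) for e in events], columns=EVENTS_COLUMNS)


def read_wav(path: str | Path, ear: str = "unknown",
             calibration_db: float | None = None) -> EarCanalRecording:
    """Load a mono WAV as an :class:`EarCanalRecording`.

    Integer PCM is rescaled to [-1, 1); float data is taken as-is.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise ValueError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    kwargs = {} if calibration_db is None else {"calibration_db": calibration_db}
    return EarCanalRecording(np.asarray(data, dtype=np.float64), float(rate),
                             ear, **kwargs)
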