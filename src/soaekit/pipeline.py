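"""End-to-end analysis: detection -> filters -> ear selection -> measurement
-> composites -> linear models, with per-stage counts and exclusion logging.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import spectral, stats, suppression, tables
from .spectral import NoSOAEsError
from .types import EarCanalRecording, SOAEPeak, STFTParams, TASK_COLUMNS

__all__ = ["DetectionSettings", "PipelineResult", "detect_subject_peaks",
           "analyze_dataset"]

log = logging.getLogger("soaekit")


@dataclass(frozen=True)
class DetectionSettings:
    """Thresholds for candidate picking and the two exclusion filters."""

    snr_threshold_db: float = 6.0
    fmin_hz: float = 1000.0
    fmax_hz: float = 10000.0
    floor_bandwidth_hz: float = 200.0
    min_separation_hz: float = 10.0
    stability_threshold_db: float = 6.0
    line_tolerance_hz: float = 5.0
    line_fundamental_hz: float = 60.0
    track_halfwidth_hz: float = 25.0
    window_s: float = 0.5
    min_frames: int = 3


@dataclass
class PipelineResult:
    peaks: pd.DataFrame
    measurements: pd.DataFrame
    composites: pd.DataFrame
    fits: dict
    counts: dict = field(default_factory=dict)
    excluded_subjects: list = field(default_factory=list)


def detect_subject_peaks(
    baseline: EarCanalRecording,
    params: STFTParams,
    settings: DetectionSettings,
) -> list[SOAEPeak]:
    """Detect candidates in one ear's baseline and apply both filters."""
    spectrum, segments = spectral.baseline_spectra_with_segments(baseline,
                                                                 params)
    peaks = spectral.detect_soae_candidates(
        spectrum, settings.snr_threshold_db, settings.fmin_hz, settings.fmax_hz,
        settings.floor_bandwidth_hz, settings.min_separation_hz,
    )
    peaks = spectral.stability_filter(
        baseline, peaks, params, settings.stability_threshold_db,
        halfwidth_hz=settings.track_halfwidth_hz, segment_spectra=segments,
    )
    peaks = spectral.line_noise_filter(
        peaks, settings.line_tolerance_hz, settings.line_fundamental_hz,
    )
    return peaks


def _peak_rows(subject_id: str, ear: str, peaks: list[SOAEPeak]) -> list[dict]:
    return [
        {"subject_id": subject_id, "ear": ear, "frequency_hz": p.frequency,
         "baseline_level_db": p.baseline_level, "stability_sd_db": p.stability_sd,
         "excluded_by": p.excluded_by}
        for p in peaks
    ]


def analyze_dataset(
    dataset_dir: str | Path,
    params: STFTParams | None = None,
    settings: DetectionSettings | None = None,
    loadings: dict | None = None,
    se: str = "ols",
    measure_suppression: bool = True,
) -> PipelineResult:
    """Run the full analysis over a generated dataset directory.

    Subjects with no surviving SOAEs are excluded (and logged), not fatal.
    The three fits (cognitive, group, residualized group) are returned when
    the surviving cohort spans at least two language groups. With
    ``measure_suppression=False`` the run stops after detection and ear
    selection (peak table only).
    """
    dataset_dir = Path(dataset_dir)
    params = params or STFTParams()
    settings = settings or DetectionSettings()

    metadata = tables.read_table(dataset_dir / "subjects.csv",
                                 tables.METADATA_COLUMNS)
    events = tables.read_events(dataset_dir / "events.csv")
    gt_path = dataset_dir / "ground_truth.json"
    calibration_db = None
    if gt_path.exists():
        calibration_db = json.loads(gt_path.read_text()).get("calibration_db")

    peak_rows: list[dict] = []
    measurement_frames: list[pd.DataFrame] = []
    excluded: list[str] = []
    analyzed: list[str] = []
    for sid in metadata["subject_id"]:
        ear_peaks = {}
        for ear in ("left", "right"):
            rec = tables.read_wav(dataset_dir / "audio" / f"{sid}_{ear}_baseline.wav",
                                  ear, calibration_db)
            ear_peaks[ear] = detect_subject_peaks(rec, params, settings)
            peak_rows.extend(_peak_rows(sid, ear, ear_peaks[ear]))
        try:
            test_ear = spectral.select_test_ear(
                ear_peaks["left"], ear_peaks["right"],
                settings.fmin_hz, settings.fmax_hz,
            )
        except NoSOAEsError:
            excluded.append(sid)
            log.info("subject %s excluded: no surviving SOAEs", sid)
            continue
        if not measure_suppression:
            analyzed.append(sid)
            continue
        task = tables.read_wav(dataset_dir / "audio" / f"{sid}_task.wav",
                               test_ear, calibration_db)
        gram = spectral.stft(task, params)
        surviving = [p for p in ear_peaks[test_ear]
                     if p.surviving and settings.fmin_hz <= p.frequency
                     <= settings.fmax_hz]
        subject_events = [e for e in events if e.subject_id == sid]
        measured = suppression.measure_all(
            gram, subject_events, surviving, settings.window_s,
            settings.track_halfwidth_hz, settings.min_frames,
        )
        measurement_frames.append(measured)
        analyzed.append(sid)
        log.info("subject %s: ear=%s, %d surviving SOAEs, %d trials",
                 sid, test_ear, len(surviving), len(subject_events))

    peaks = pd.DataFrame(peak_rows, columns=tables.PEAKS_COLUMNS)
    measurements = (pd.concat(measurement_frames, ignore_index=True)
                    if measurement_frames
                    else pd.DataFrame(columns=tables.MEASUREMENT_COLUMNS))

    tasks = metadata.set_index("subject_id")[list(TASK_COLUMNS)]
    composites = stats.composites_from_tasks(tasks, loadings)

    meta = metadata.copy()
    # test ear per subject from the peaks table (the ear actually measured)
    measured_sids = set(measurements["subject_id"].unique())
    ear_of = {}
    for sid in measured_sids:
        freqs = set(measurements.loc[measurements["subject_id"] == sid,
                                     "soae_frequency_hz"])
        sub = peaks[(peaks["subject_id"] == sid)
                    & (peaks["frequency_hz"].isin(freqs))]
        ear_of[sid] = sub["ear"].iloc[0] if len(sub) else "unknown"
    meta["test_ear"] = meta["subject_id"].map(ear_of)

    fits: dict = {}
    usable = measurements[measurements["missing_reason"].fillna("") == ""]
    groups_present = meta[meta["subject_id"].isin(measured_sids)]["group"].nunique()
    if not usable.empty and groups_present >= 2:
        cog = stats.cognitive_model(measurements, composites, se=se)
        fits["cognitive"] = cog
        fits["group"] = stats.group_model(measurements, meta, se=se)
        try:
            fits["group_with_ear"] = stats.group_model(measurements, meta,
                                                       include_ear=True, se=se)
        except ValueError as exc:  # e.g. every analyzed subject same test ear
            log.warning("ear-covariate model skipped: %s", exc)
        fits["residualized_group"] = stats.residualized_group_model(
            cog, measurements, meta, se=se)
    elif not usable.empty:
        log.warning("only one language group measured; group models skipped")

    counts = {
        "subjects_in": int(len(metadata)),
        "subjects_excluded": int(len(excluded)),
        "subjects_analyzed": int(len(analyzed)),
        "soaes_detected": int(len(peaks)),
        "excluded_stability": int((peaks["excluded_by"] == "stability").sum()),
        "excluded_line_noise": int((peaks["excluded_by"] == "line_noise").sum()),
        "rows_measured": int(len(measurements)),
        "rows_modeled": int(len(usable)),
    }
    assert counts["subjects_in"] == (counts["subjects_excluded"]
                                     + counts["subjects_analyzed"])
    return PipelineResult(peaks, measurements, composites, fits, counts,
                          excluded)


def fits_report(fits: dict) -> pd.DataFrame:
    """Stack every fitted model's term table into one long report frame."""
    frames = []
    for name, fit in fits.items():
        rep = fit.report().reset_index(names="term")
        rep.insert(0, "model", name)
        frames.append(rep)
    return (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["model", "term", "beta", "se", "t",
                                       "p", "n", "df"]))
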