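"""Synthetic cohorts with known ground truth.

Emulates the study conditions the analysis assumes: per subject, a pair of
3-min silent baseline ear-canal recordings and one task recording from the
test ear covering a block-structured trial sequence (speech onset 1.5 s
after each trial onset), containing 1-3 narrowband SOAE oscillators between
~1 and 6.4 kHz at baseline levels around -5 to -3 dB SPL, a broadband noise
floor, and 60 Hz line-noise harmonics. During each contralateral speech
sound the oscillators are attenuated by a fast-onset exponential gain
envelope whose asymptotic magnitude depends on subject covariates:

    magnitude_i = max(0, mu - (b_control*C_i + b_wm*W_i
                               + b_interaction*C_i*W_i
                               + b_group*bilingual_i
                               + b_baseline*(L_i - Lbar)) - eps_i)

so that the expected trial delta (stimulus minus baseline, in dB) is
``-magnitude_i`` and the coefficients are recovered with their own signs by
the delta models. The composites C and W are built from five simulated task
scores pushed through the stats module's composite operation.

Two fidelity levels are provided: :func:`generate_cohort` renders full audio
to disk, while :func:`simulate_measurements` emits the per-trial measurement
table directly from the ground truth plus trial noise — the statistical
layer without the audio path — for fast calibration simulations.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import lfilter

from . import stats
from .spectral import analysis_window
from .suppression import MEASUREMENT_COLUMNS
from .types import (
    DEFAULT_CALIBRATION_DB,
    GROUPS,
    TASK_COLUMNS,
    STFTParams,
    TrialEvent,
)

__all__ = [
    "OscillatorSpec",
    "SuppressionSpec",
    "CohortConfig",
    "simulate_soae_waveform",
    "simulate_line_noise",
    "suppression_envelope",
    "white_noise_sigma",
    "make_trial_events",
    "render_subject_recording",
    "generate_cohort",
    "simulate_measurements",
    "load_ground_truth",
]

SYLLABLES = ("ba", "da", "ga", "pa", "ta", "ka")


@dataclass(frozen=True)
class OscillatorSpec:
    """One narrowband emission: frequency, target baseline level, jitter.

    Frequency jitter is a slow Ornstein-Uhlenbeck wander (SD in Hz,
    correlation time ``jitter_timescale_s``); amplitude jitter is an OU
    process in dB. ``level_db`` may be ``-inf`` for a silent oscillator.
    """

    frequency: float
    level_db: float
    frequency_jitter_sd: float = 0.0
    amplitude_jitter_sd: float = 0.0
    jitter_timescale_s: float = 1.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("oscillator frequency must be > 0")
        if math.isnan(self.level_db) or self.level_db == math.inf:
            raise ValueError("oscillator level must be finite or -inf")
        if self.frequency_jitter_sd < 0 or self.amplitude_jitter_sd < 0:
            raise ValueError("jitter SDs must be >= 0")


@dataclass(frozen=True)
class SuppressionSpec:
    """Efferent gain reduction: asymptotic magnitude, latency, time constant.

    During contralateral stimulation the oscillator gain decays
    exponentially toward ``-magnitude_db`` (after ``onset_latency_s``) with
    time constant ``time_constant_s``, and recovers toward 0 dB after
    stimulus offset with the same time constant — the fast (tens of
    milliseconds) component of the efferent effect.
    """

    magnitude_db: float
    onset_latency_s: float = 0.01
    time_constant_s: float = 0.03

    def __post_init__(self) -> None:
        if self.magnitude_db < 0:
            raise ValueError("suppression magnitude must be >= 0")
        if self.time_constant_s <= 0:
            raise ValueError("time constant must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings: cohort sizes, trial structure, effects, acoustics.

    Effect coefficients are on the trial-delta (dB) scale; defaults mirror
    the observed direction of each effect (higher Control -> more
    suppression, higher Working Memory -> less, bilingual -> more).
    """

    n_mono: int = 11
    n_late_bi: int = 10
    n_early_bi: int = 11
    n_no_soae: int = 0  # extra subjects without emissions (excluded downstream)
    n_trials: int = 240
    n_blocks: int = 10
    # generative effects (dB per unit predictor, on the delta scale)
    mu_suppression_db: float = 1.0
    b_control: float = -0.10
    b_wm: float = 0.32
    b_interaction: float = -0.09
    b_group: float = -0.83
    b_baseline_level: float = 0.0
    residual_sd: float = 0.15
    trial_noise_sd: float = 0.40  # measurement-level simulator only
    clip_magnitude: bool = True  # floor suppression at 0 dB (audio needs this)
    # trial timing (s)
    lead_in_s: float = 2.0
    trial_period_s: float = 5.5
    speech_delay_s: float = 1.5
    speech_duration_s: float = 0.5
    onset_latency_s: float = 0.01
    time_constant_s: float = 0.03
    # acoustics
    sample_rate: float = 44100.0
    baseline_duration_s: float = 180.0
    calibration_db: float = DEFAULT_CALIBRATION_DB
    noise_floor_db: float = -25.0
    line_fundamental_hz: float = 60.0
    n_line_harmonics: int = 20
    line_level_first_db: float = -8.0
    line_level_slope_db: float = -0.5  # per harmonic index
    # emissions
    soae_fmin: float = 1060.0
    soae_fmax: float = 6450.0
    level_mean_mono: float = -4.9
    level_mean_bilingual: float = -2.9
    level_sd: float = 1.2
    frequency_jitter_sd: float = 1.0
    amplitude_jitter_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials % self.n_blocks != 0:
            raise ValueError(
                f"n_trials ({self.n_trials}) must be divisible by n_blocks "
                f"({self.n_blocks})"
            )
        if self.residual_sd < 0 or self.trial_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.n_mono + self.n_late_bi + self.n_early_bi + self.n_no_soae

    def line_levels(self) -> list[float]:
        return [self.line_level_first_db + self.line_level_slope_db * k
                for k in range(self.n_line_harmonics)]


def _ou_process(n: int, sd: float, timescale_s: float, sample_rate: float,
                rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples (mean 0, stated SD).

    Simulated on a coarse grid (50 steps per correlation time) and linearly
    interpolated to the audio rate; the process is far slower than the
    audio rate, so nothing is lost and rendering stays cheap.
    """
    if sd == 0:
        return np.zeros(n)
    coarse_rate = max(50.0 / timescale_s, 2.0)
    n_coarse = int(math.ceil(n / sample_rate * coarse_rate)) + 2
    rho = math.exp(-1.0 / (timescale_s * coarse_rate))
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    noise = rng.standard_normal(n_coarse) * innov_sd
    noise[0] = rng.standard_normal() * sd  # stationary start
    coarse = lfilter([1.0], [1.0, -rho], noise)
    t = _sample_times(n, sample_rate)
    return np.interp(t, np.arange(n_coarse) / coarse_rate, coarse)


def simulate_soae_waveform(
    spec: OscillatorSpec,
    duration_s: float,
    sample_rate: float,
    seed: int,
    calibration_db: float = DEFAULT_CALIBRATION_DB,
) -> np.ndarray:
    """Render one emission as an amplitude-stabilized jittered sinusoid.

    The long-window spectrum of the result peaks at ``spec.frequency``
    (within one analysis bin) and at ``spec.level_db`` under the dataset
    calibration. Deterministic given ``seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if sample_rate < 2.5 * spec.frequency:
        raise ValueError(
            f"oscillator at {spec.frequency:.0f} Hz needs a sample rate of at "
            f"least 2.5x its frequency ({2.5 * spec.frequency:.0f} Hz); got "
            f"{sample_rate:.0f} Hz (Nyquist {sample_rate / 2:.0f} Hz)"
        )
    n = int(round(duration_s * sample_rate))
    if spec.level_db == -math.inf:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    phase0 = rng.uniform(0, 2 * math.pi)
    amp0 = 10.0 ** ((spec.level_db - calibration_db) / 20.0)
    if spec.frequency_jitter_sd == 0:
        phase = phase0 + 2.0 * math.pi * spec.frequency * _sample_times(n, sample_rate)
    else:
        freq = spec.frequency + _ou_process(
            n, spec.frequency_jitter_sd, spec.jitter_timescale_s, sample_rate,
            rng,
        )
        phase = phase0 + 2.0 * math.pi * np.cumsum(freq) / sample_rate
    wave = np.sin(phase)
    if spec.amplitude_jitter_sd > 0:
        amp_db = _ou_process(
            n, spec.amplitude_jitter_sd, spec.jitter_timescale_s, sample_rate,
            rng,
        )
        wave *= 10.0 ** (amp_db / 20.0)
    return amp0 * wave


def simulate_line_noise(
    duration_s: float,
    sample_rate: float,
    levels_db: Sequence[float],
    fundamental_hz: float = 60.0,
    calibration_db: float = DEFAULT_CALIBRATION_DB,
) -> np.ndarray:
    """Sum of mains harmonics k*fundamental, k = 1..len(levels_db)."""
    if len(levels_db) < 1:
        raise ValueError("need at least one harmonic level")
    top = len(levels_db) * fundamental_hz
    if top >= sample_rate / 2:
        raise ValueError(
            f"harmonic {len(levels_db)} at {top:.0f} Hz is at or above "
            f"Nyquist ({sample_rate / 2:.0f} Hz)"
        )
    return _line_noise_cached(
        int(round(duration_s * sample_rate)), float(sample_rate),
        tuple(float(v) for v in levels_db), float(fundamental_hz),
        float(calibration_db),
    )


@lru_cache(maxsize=8)
def _sample_times(n: int, sample_rate: float) -> np.ndarray:
    return np.arange(n) / sample_rate


@lru_cache(maxsize=4)
def _line_noise_cached(n: int, sample_rate: float, levels_db: tuple,
                       fundamental_hz: float, calibration_db: float) -> np.ndarray:
    # mains interference is shared across recordings, so one render per shape;
    # when the fundamental divides the sample rate the waveform is periodic
    # and one period can be tiled
    period = sample_rate / fundamental_hz
    if abs(period - round(period)) < 1e-9 and n > 2 * period:
        base = _line_noise_cached(int(round(period)), sample_rate, levels_db,
                                  fundamental_hz, calibration_db)
        reps = int(math.ceil(n / period))
        return np.tile(base, reps)[:n]
    t = _sample_times(n, sample_rate)
    out = np.zeros(n)
    for k, level in enumerate(levels_db, start=1):
        amp = 10.0 ** ((level - calibration_db) / 20.0)
        out += amp * np.sin(2.0 * math.pi * k * fundamental_hz * t)
    return out


def suppression_envelope(
    spec: SuppressionSpec,
    events: Sequence[TrialEvent],
    duration_s: float,
    sample_rate: float,
    speech_duration_s: float = 0.5,
) -> np.ndarray:
    """Per-sample gain trace in dB: 0 outside stimulation.

    During each speech sound the gain decays exponentially toward
    ``-magnitude_db`` (after the onset latency) and recovers toward 0 after
    offset, both with the spec's time constant. An empty event list yields
    an all-zero trace.
    """
    n = int(round(duration_s * sample_rate))
    env = np.zeros(n)
    if not events or spec.magnitude_db == 0:
        return env
    onsets = [e.speech_onset_s for e in events]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("events must be sorted by speech onset")
    tau = spec.time_constant_s
    value = 0.0  # envelope value carried across segment boundaries
    t_prev = 0.0
    for onset in onsets:
        t_on = onset + spec.onset_latency_s
        t_off = onset + speech_duration_s
        if t_off <= t_on:
            raise ValueError("speech duration must exceed the onset latency")
        # recovery (or initial silence) segment [t_prev, t_on): decay to 0
        value = _fill_exponential(env, t_prev, t_on, value, 0.0, tau, sample_rate)
        # stimulation segment [t_on, t_off): decay toward -magnitude
        value = _fill_exponential(env, t_on, t_off, value, -spec.magnitude_db,
                                  tau, sample_rate)
        t_prev = t_off
    _fill_exponential(env, t_prev, duration_s, value, 0.0, tau, sample_rate)
    return env


def _fill_exponential(env: np.ndarray, t0: float, t1: float, start: float,
                      target: float, tau: float, sample_rate: float) -> float:
    """Write target + (start-target)*exp(-(t-t0)/tau) into env over [t0, t1)."""
    i0 = max(0, int(math.ceil(t0 * sample_rate - 1e-9)))
    i1 = min(env.size, int(math.ceil(t1 * sample_rate - 1e-9)))
    if i1 > i0:
        t = np.arange(i0, i1) / sample_rate - t0
        env[i0:i1] = target + (start - target) * np.exp(-t / tau)
    dt = max(0.0, t1 - t0)
    return target + (start - target) * math.exp(-dt / tau)


def white_noise_sigma(
    noise_floor_db: float,
    calibration_db: float = DEFAULT_CALIBRATION_DB,
    params: STFTParams | None = None,
) -> float:
    """Waveform-sample SD giving the stated mean spectrum level (dB).

    Under the package's amplitude normalization (2/sum(window)), white noise
    of sample SD sigma has expected per-bin power 4*sigma^2*sum(w^2)/sum(w)^2.
    """
    params = params or STFTParams()
    w = analysis_window(params)
    target_power = 10.0 ** ((noise_floor_db - calibration_db) / 10.0)
    return math.sqrt(target_power * np.sum(w) ** 2 / (4.0 * np.sum(w ** 2)))


def make_trial_events(
    subject_id: str,
    n_trials: int,
    n_blocks: int,
    lead_in_s: float = 2.0,
    trial_period_s: float = 5.5,
    speech_delay_s: float = 1.5,
    rng: np.random.Generator | None = None,
    accuracy: float = 0.67,
) -> list[TrialEvent]:
    """Regularly spaced trials in equal blocks, speech 1.5 s after onset."""
    if n_trials % n_blocks != 0:
        raise ValueError("n_trials must be divisible by n_blocks")
    per_block = n_trials // n_blocks
    rng = rng or np.random.default_rng(0)
    events = []
    for k in range(n_trials):
        onset = lead_in_s + k * trial_period_s
        syllable = SYLLABLES[rng.integers(len(SYLLABLES))]
        if rng.random() < accuracy:
            response = syllable
        else:
            response = SYLLABLES[rng.integers(len(SYLLABLES))]
        events.append(TrialEvent(
            subject_id=subject_id,
            trial_index=k,
            block=k // per_block,
            trial_onset_s=onset,
            speech_onset_s=onset + speech_delay_s,
            syllable=syllable,
            response=response,
        ))
    return events


def render_subject_recording(
    oscillators: Sequence[OscillatorSpec],
    duration_s: float,
    sample_rate: float,
    rng: np.random.Generator,
    calibration_db: float = DEFAULT_CALIBRATION_DB,
    noise_floor_db: float = -25.0,
    line_levels_db: Sequence[float] = (),
    line_fundamental_hz: float = 60.0,
    suppression: SuppressionSpec | None = None,
    events: Sequence[TrialEvent] | None = None,
    speech_duration_s: float = 0.5,
) -> np.ndarray:
    """One ear-canal waveform: emissions (x gain envelope) + line + noise.

    The suppression envelope is applied to the emission sum only; line noise
    and the microphone noise floor are unaffected by efferent gain.
    """
    n = int(round(duration_s * sample_rate))
    soae_sum = np.zeros(n)
    for spec in oscillators:
        seed = int(rng.integers(2 ** 31))
        soae_sum += simulate_soae_waveform(spec, duration_s, sample_rate, seed,
                                           calibration_db)
    if suppression is not None and events:
        env = suppression_envelope(suppression, events, duration_s, sample_rate,
                                   speech_duration_s)
        soae_sum *= 10.0 ** (env / 20.0)
    out = soae_sum
    if line_levels_db:
        out = out + simulate_line_noise(duration_s, sample_rate, line_levels_db,
                                        line_fundamental_hz, calibration_db)
    sigma = white_noise_sigma(noise_floor_db, calibration_db,
                              STFTParams(sample_rate=sample_rate))
    out = out + sigma * rng.standard_normal(n)
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# cohort-level truth
# ---------------------------------------------------------------------------

_GROUP_LATENTS = {
    # latent (control, working-memory) means per language group
    "mono": (-0.65, 0.48),
    "late_bi": (0.26, -0.54),
    "early_bi": (0.41, 0.01),
}


def _draw_subjects(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Subject table: group, covariates, five task scores."""
    groups = (["mono"] * config.n_mono + ["late_bi"] * config.n_late_bi
              + ["early_bi"] * config.n_early_bi)
    has_soae = [True] * len(groups)
    for k in range(config.n_no_soae):
        groups.append(GROUPS[k % len(GROUPS)])
        has_soae.append(False)
    rows = []
    for i, (group, soae) in enumerate(zip(groups, has_soae)):
        sid = f"S{i + 1:03d}"
        mu_c, mu_w = _GROUP_LATENTS[group]
        c = mu_c + rng.standard_normal()
        w = mu_w + rng.standard_normal()
        task_noise = 0.3
        tasks = {
            "vocabulary": 0.223 * w + task_noise * rng.standard_normal(),
            "flanker": 0.922 * c + task_noise * rng.standard_normal(),
            "working_memory": 0.999 * w + task_noise * rng.standard_normal(),
            "card_sort": 0.509 * c - 0.119 * w + task_noise * rng.standard_normal(),
            "pattern": 0.525 * c - 0.128 * w + task_noise * rng.standard_normal(),
        }
        if group == "mono":
            aoa = float(rng.integers(0, 2) * 0.5)
            eng_prof = np.clip(9.79 + 0.4 * rng.standard_normal(), 0, 10)
            kor_prof = float("nan")
        elif group == "late_bi":
            aoa = float(np.clip(9.11 + 1.45 * rng.standard_normal(), 7.1, 15))
            eng_prof = np.clip(8.59 + 0.98 * rng.standard_normal(), 0, 10)
            kor_prof = np.clip(9.0 + 0.97 * rng.standard_normal(), 0, 10)
        else:
            aoa = float(np.clip(3.0 + 1.89 * rng.standard_normal(), 0, 6.9))
            eng_prof = np.clip(9.36 + 0.75 * rng.standard_normal(), 0, 10)
            kor_prof = np.clip(8.06 + 2.19 * rng.standard_normal(), 0, 10)
        rows.append({
            "subject_id": sid, "group": group, "has_soae": soae,
            "english_aoa": round(aoa, 2),
            "english_prof": round(float(eng_prof), 2),
            "korean_prof": round(float(kor_prof), 2)
            if not math.isnan(kor_prof) else float("nan"),
            **{k: round(v, 4) for k, v in tasks.items()},
        })
    return pd.DataFrame(rows)


def _draw_oscillators(config: CohortConfig, group: str,
                      rng: np.random.Generator) -> list[OscillatorSpec]:
    """1-3 emissions on the 2 Hz analysis grid, clear of line harmonics."""
    n_osc = int(rng.integers(1, 4))
    level_mean = (config.level_mean_mono if group == "mono"
                  else config.level_mean_bilingual)
    freqs: list[float] = []
    attempts = 0
    while len(freqs) < n_osc:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place oscillators; constraints too tight")
        f = rng.uniform(config.soae_fmin, config.soae_fmax)
        f = round(f / 2.0) * 2.0  # snap to the 2 Hz analysis grid
        k = round(f / config.line_fundamental_hz)
        # keep line harmonics outside the +/-25 Hz tracking window (the
        # widest margin the 60 Hz harmonic spacing allows is < 30 Hz)
        if abs(f - k * config.line_fundamental_hz) < 26.0:
            continue
        if any(abs(f - g) < 120.0 for g in freqs):
            continue
        freqs.append(f)
    return [
        OscillatorSpec(
            frequency=f,
            level_db=float(np.clip(level_mean + config.level_sd
                                   * rng.standard_normal(), -8.0, 0.0)),
            frequency_jitter_sd=config.frequency_jitter_sd,
            amplitude_jitter_sd=config.amplitude_jitter_sd,
        )
        for f in sorted(freqs)
    ]


def draw_cohort_truth(config: CohortConfig,
                      rng: np.random.Generator) -> dict:
    """Sample everything the generative model fixes before audio rendering.

    Returns a dict with the subject table (including composites), per-subject
    oscillators per ear, test ears, and true suppression magnitudes.
    """
    subjects = _draw_subjects(config, rng)
    tasks = subjects.set_index("subject_id")[list(TASK_COLUMNS)]
    composites = stats.composites_from_tasks(tasks)
    subjects = subjects.merge(
        composites.rename(columns={"control": "control_composite",
                                   "working_memory": "wm_composite"}),
        left_on="subject_id", right_index=True,
    )
    oscillators: dict[str, dict[str, list[OscillatorSpec]]] = {}
    test_ears: dict[str, str] = {}
    mean_levels = {}
    for row in subjects.itertuples():
        if row.has_soae:
            ears = {"left": _draw_oscillators(config, row.group, rng),
                    "right": _draw_oscillators(config, row.group, rng)}
        else:
            ears = {"left": [], "right": []}
        oscillators[row.subject_id] = ears
        n_left = sum(1 for o in ears["left"] if 1000 <= o.frequency <= 10000)
        n_right = sum(1 for o in ears["right"] if 1000 <= o.frequency <= 10000)
        test_ears[row.subject_id] = "left" if n_left > n_right else "right"
        test_osc = ears[test_ears[row.subject_id]]
        mean_levels[row.subject_id] = (
            float(np.mean([o.level_db for o in test_osc])) if test_osc
            else float("nan")
        )
    subjects["test_ear"] = subjects["subject_id"].map(test_ears)
    subjects["mean_soae_level"] = subjects["subject_id"].map(mean_levels)
    level_center = float(np.nanmean(subjects["mean_soae_level"]))
    bilingual = subjects["group"].isin(["early_bi", "late_bi"]).astype(float)
    c = subjects["control_composite"].to_numpy()
    w = subjects["wm_composite"].to_numpy()
    level_dev = np.nan_to_num(subjects["mean_soae_level"].to_numpy()
                              - level_center)
    eps = config.residual_sd * rng.standard_normal(len(subjects))
    magnitude = (
        config.mu_suppression_db
        - (config.b_control * c + config.b_wm * w
           + config.b_interaction * c * w
           + config.b_group * bilingual.to_numpy()
           + config.b_baseline_level * level_dev)
        - eps
    )
    if config.clip_magnitude:
        magnitude = np.maximum(0.0, magnitude)
    subjects["true_magnitude_db"] = magnitude
    return {
        "config": config,
        "subjects": subjects,
        "composites": composites,
        "oscillators": oscillators,
    }


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> Path:
    """Write a full synthetic dataset: WAVs, tables, and ground truth.

    Layout::

        out_dir/
          audio/<sid>_<ear>_baseline.wav   both ears, 3 min silence
          audio/<sid>_task.wav             test ear, all trials
          events.csv  subjects.csv  ground_truth.json

    Fully reproducible from ``config`` (including its seed): identical
    configurations produce byte-identical files.
    """
    out_dir = Path(out_dir)
    audio_dir = out_dir / "audio"
    audio_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = draw_cohort_truth(config, rng)
    subjects: pd.DataFrame = truth["subjects"]
    task_duration = (config.lead_in_s + config.n_trials * config.trial_period_s
                     + config.trial_period_s)
    all_events = []
    fs = config.sample_rate
    for row in subjects.itertuples():
        sid = row.subject_id
        ears = truth["oscillators"][sid]
        for ear in ("left", "right"):
            wave = render_subject_recording(
                ears[ear], config.baseline_duration_s, fs, rng,
                config.calibration_db, config.noise_floor_db,
                config.line_levels(), config.line_fundamental_hz,
            )
            _write_wav(audio_dir / f"{sid}_{ear}_baseline.wav", fs, wave)
        events = make_trial_events(
            sid, config.n_trials, config.n_blocks, config.lead_in_s,
            config.trial_period_s, config.speech_delay_s, rng,
        )
        all_events.extend(events)
        suppression = SuppressionSpec(
            float(row.true_magnitude_db), config.onset_latency_s,
            config.time_constant_s,
        )
        wave = render_subject_recording(
            ears[row.test_ear], task_duration, fs, rng,
            config.calibration_db, config.noise_floor_db,
            config.line_levels(), config.line_fundamental_hz,
            suppression, events, config.speech_duration_s,
        )
        _write_wav(audio_dir / f"{sid}_task.wav", fs, wave)

    events_df = pd.DataFrame([asdict(e) for e in all_events])
    events_df.to_csv(out_dir / "events.csv", index=False)
    meta_cols = ["subject_id", "group", "english_aoa", "english_prof",
                 "korean_prof", *TASK_COLUMNS]
    subjects[meta_cols].to_csv(out_dir / "subjects.csv", index=False)
    _write_ground_truth(out_dir / "ground_truth.json", truth)
    return out_dir


def _write_wav(path: Path, sample_rate: float, samples: np.ndarray) -> None:
    try:
        wavfile.write(path, int(sample_rate), samples.astype(np.float32))
    except OSError as exc:  # surface the file path with the failure
        raise OSError(f"failed writing {path}: {exc}") from exc


def _write_ground_truth(path: Path, truth: dict) -> None:
    subjects: pd.DataFrame = truth["subjects"]
    payload = {
        "config": asdict(truth["config"]),
        "calibration_db": truth["config"].calibration_db,
        "subjects": {},
    }
    for row in subjects.itertuples():
        sid = row.subject_id
        payload["subjects"][sid] = {
            "group": row.group,
            "test_ear": row.test_ear,
            "true_magnitude_db": float(row.true_magnitude_db),
            "control_composite": float(row.control_composite),
            "wm_composite": float(row.wm_composite),
            "oscillators": {
                ear: [{"frequency": o.frequency, "level_db": o.level_db,
                       "frequency_jitter_sd": o.frequency_jitter_sd,
                       "amplitude_jitter_sd": o.amplitude_jitter_sd}
                      for o in truth["oscillators"][sid][ear]]
                for ear in ("left", "right")
            },
        }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_ground_truth(dataset_dir: str | Path) -> dict:
    return json.loads((Path(dataset_dir) / "ground_truth.json").read_text())


# ---------------------------------------------------------------------------
# measurement-level simulator (no audio)
# ---------------------------------------------------------------------------


def simulate_measurements(config: CohortConfig,
                          seed: int | None = None) -> dict:
    """Per-trial measurement table straight from the generative model.

    Skips audio rendering and spectral analysis: each (trial x SOAE) delta is
    ``-magnitude_i`` plus independent N(0, trial_noise_sd) measurement noise.
    Used for calibration simulations of the statistical layer.

    Returns a dict with ``measurements``, ``metadata``, ``composites`` and
    ``truth`` (the full cohort ground-truth dict).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = draw_cohort_truth(config, rng)
    subjects: pd.DataFrame = truth["subjects"]
    rows = []
    for row in subjects.itertuples():
        if not row.has_soae:
            continue
        oscillators = truth["oscillators"][row.subject_id][row.test_ear]
        for osc in oscillators:
            deltas = (-row.true_magnitude_db
                      + config.trial_noise_sd
                      * rng.standard_normal(config.n_trials))
            for k in range(config.n_trials):
                rows.append({
                    "subject_id": row.subject_id,
                    "trial_index": k,
                    "soae_frequency_hz": osc.frequency,
                    "baseline_level_db": osc.level_db,
                    "stimulus_level_db": osc.level_db + deltas[k],
                    "delta_db": deltas[k],
                    "n_frames_baseline": 5,
                    "n_frames_stimulus": 5,
                    "missing_reason": "",
                })
    measurements = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    meta_cols = ["subject_id", "group", "english_aoa", "english_prof",
                 "korean_prof", "test_ear", *TASK_COLUMNS]
    return {
        "measurements": measurements,
        "metadata": subjects[meta_cols].copy(),
        "composites": truth["composites"],
        "truth": truth,
    }
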