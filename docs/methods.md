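# Methods

## The measurement

A healthy cochlea emits narrowband sounds — spontaneous otoacoustic
emissions (SOAEs) — that a sealed-ear-canal microphone can record without
any stimulus. Sound played to the *opposite* ear drives the medial
olivocochlear (MOC) efferent pathway, which turns down outer-hair-cell
amplification and thereby suppresses SOAE level. The package quantifies
that suppression trial by trial during a contralateral speech task and
relates it to subject-level covariates: two cognitive composites
("Control" and "Working Memory") and language-group membership
(monolingual vs. early/late bilingual).

The pipeline is: identify SOAEs in a 3-minute silent baseline from both
ears; exclude unstable peaks and peaks near mains harmonics; pick the test
ear; track each surviving emission through the task recording; average its
level in a 500-ms pre-trial window and a 500-ms window from speech onset;
model the per-trial level difference (ΔdB, negative = suppression).

## Spectral analysis

All spectra come from a short-time Fourier transform with a 16,384-point
Hamming window (371.5 ms at 44.1 kHz), hop 4,096 (92.9 ms), zero-padded to
22,050 points, giving exactly 2 Hz bins. Frame timestamps use the
window-center convention, so spectral smearing is symmetric around events.
Magnitudes are scaled by 2/Σw, so a sinusoid at a bin center reads its
waveform amplitude; dB SPL is defined by a dataset-wide calibration
constant (level of a full-scale sinusoid; 90 dB SPL by default in the
synthetic world, stored in each dataset's ground-truth sidecar). Magnitudes
are floored at −200 dB before taking logs.

Baseline spectra average frames in the power domain and convert the mean
to dB — unbiased for stationary signals. The 500-ms measurement windows
instead average the tracked-peak levels in the dB domain, matching the
"average peak level" convention; for the level variances involved the two
conventions differ by well under 0.1 dB.

**Peak picking.** No universal SOAE criterion exists, so detection is
parameterized and conservative: a candidate is a local maximum at least
6 dB (configurable) above a 200 Hz median-smoothed noise floor within
1–10 kHz; when two candidates fall within 10 Hz, the higher survives.

**Exclusion filters.** (1) Stability: each peak's level is measured in the
first four non-overlapping 30-s baseline segments; a sample SD (n−1)
strictly greater than 6 dB excludes the peak — an SD of exactly 6.0 dB is
kept. (2) Line noise: a peak within 5 Hz (inclusive) of any multiple of
60 Hz is excluded. Both filters only set flags; they never alter frequency
or level, so their composition commutes (stability takes precedence when
both apply). The test ear is the one with more surviving peaks in
1–10 kHz; ties go to the right ear. Subjects with no surviving SOAE in
either ear are excluded, not fatal.

**Tracking.** Within each frame, the emission is the highest local maximum
within an inclusive ±25 Hz window around its baseline frequency; a frame
with no local maximum there (e.g. a monotonic stretch of spectrum) is
dropped. A measurement window needs at least 3 usable frames (of the 5–6
whose centers fall in 500 ms), otherwise the observation is flagged with a
machine-readable reason and excluded from models.

## Statistical models

Composites are loading-weighted sums of z-scored task scores (sample SD,
n−1). The loadings are fixed constants from a two-factor solution over the
five tasks — Control: flanker 0.922, pattern 0.525, card sort 0.509;
Working Memory: working memory 0.999, vocabulary 0.223, card sort −0.119,
pattern −0.128. All non-blank cells are used by default; a salient-only
variant (|loading| ≥ 0.3) is available. Factor estimation itself is out of
scope — the loadings are inputs.

Three OLS models are fitted to trial-level observations:

1. cognitive: ΔdB ~ Control + WorkingMemory + Control×WorkingMemory
2. group: ΔdB ~ bilingual + baseline SOAE level (+ optionally test ear);
   the baseline-level covariate is the subject-level mean per emission
3. residualized: residuals of (1) ~ bilingual

plus, within bilinguals, ΔdB ~ age of English acquisition. Inference is
classical t by default (mirroring the plain-linear-model convention), with
two extensions the package's own calibration relies on:

- **cluster-robust SEs** (groups = subject, t at G−1 df), because trials
  are correlated within subject and naive trial-level SEs are
  anticonservative by the usual design-effect argument;
- **subject aggregation** (`aggregate="subject"`): the same design fitted
  to per-subject mean ΔdB. Because all covariates are subject-level, this
  estimates the same coefficients, and its classical t intervals are well
  calibrated at small cohort sizes, where even cluster-robust intervals
  undercover (measured: CR1 95% intervals cover ≈80–85% at 12 clusters,
  subject-level intervals ≈95–96%).

`correlation_t` converts a Pearson r to t = r√(n−2)/√(1−r²) with n−2 df.
No multiple-testing correction is applied anywhere.

## The synthetic world

The generator emulates the study conditions so that every stage can be
validated by parameter recovery:

- **Cohort**: 11 monolingual, 10 late-bilingual, 11 early-bilingual
  subjects by default (optionally extra SOAE-free subjects, which the
  pipeline must exclude); 240 trials in 10 equal blocks; speech onset
  1.5 s after trial onset; syllables of 500 ms; a 5.5-s trial period
  (the inter-trial gap is not reported anywhere authoritative; 3 s of
  post-response silence comfortably exceeds baseline window plus
  recovery).
- **Emissions**: 1–3 oscillators per ear, uniform on the 2 Hz analysis
  grid over ~1.06–6.45 kHz but at least 26 Hz from any 60 Hz multiple (the
  widest margin the harmonic spacing allows that also keeps harmonics out
  of the ±25 Hz tracking window) and 120 Hz apart. Levels are normal with
  group-dependent means (−4.9 dB SPL monolingual, −2.9 bilingual, SD 1.2),
  reflecting the observed baseline-level difference between groups. Each
  oscillator is an amplitude-stabilized sinusoid with slow
  Ornstein–Uhlenbeck frequency (SD 1 Hz) and amplitude (SD 0.2 dB) wander
  on a 1-s correlation time — enough to exercise tracking, far simpler
  than a van der Pol oscillator, and far smaller than the 25 Hz tracking
  window. The OU processes are simulated on a coarse grid (50 steps per
  correlation time) and interpolated.
- **Background**: Gaussian microphone noise at a −25 dB SPL spectrum level
  (≈20 dB below typical emission peaks), and 60 Hz mains harmonics
  (20 harmonics, −8 dB SPL at the fundamental, −0.5 dB per harmonic) that
  the line-noise filter must flag.
- **Suppression**: during each speech sound the emission gain decays
  exponentially toward −magnitude (10 ms latency, 30 ms time constant by
  default — the fast MOC component) and recovers after offset with the
  same time constant. The per-subject magnitude follows

      magnitude_i = max(0, μ − (b_C·C_i + b_W·W_i + b_CW·C_i·W_i
                                 + b_G·bilingual_i + b_L·(L_i − L̄)) − ε_i)

  with μ = 1.0 dB (a typical contralateral MOC effect; no ΔdB magnitudes
  are available to match), ε ~ N(0, 0.15 dB), and coefficients expressed
  on the ΔdB scale, so the fitted models recover the b's with their own
  signs: defaults b_C = −0.10, b_W = +0.32, b_CW = −0.09, b_G = −0.83
  (the observed effect directions: more control → more suppression, more
  working memory → less, bilingual → more). Composites enter the
  generative model exactly as the stats module computes them from the
  simulated task scores. Task scores are generated from group-shifted
  latent control/working-memory traits pushed through the same loading
  structure plus task noise, reproducing the reported group differences in
  the composites.
- **Two fidelity levels**: `generate_cohort` renders audio to disk (WAV
  float32; byte-identical for identical configurations);
  `simulate_measurements` emits the per-trial measurement table directly
  (ΔdB = −magnitude + N(0, 0.4 dB) trial noise, roughly what the audio
  path yields at the default noise floor) for calibration simulations
  where rendering audio would add nothing.

What the generator does **not** emulate: probe-fit/calibration sweeps,
middle-ear-muscle effects, ear-canal pressure drift, SOAE frequency
shifts, slow (tens of seconds) efferent adaptation, block breaks, and
response behavior beyond a nominal ~67% accuracy label. Passing tests
therefore demonstrate correctness of the analysis pipeline under the
stated generative assumptions, not robustness to every artifact of real
recordings.

## Window smearing and the recovery experiment

A 371.5-ms analysis window smears a suppression epoch confined to the
500-ms syllable: frames centered near the window edges mix suppressed and
unsuppressed signal. Measured on noise-free fixtures, a syllable-locked
step of −m dB is recovered as ≈ −0.875·m (onset- plus offset-side smear,
phase-averaged over the frame grid). The quantitative recovery experiment
therefore injects *sustained* suppression — a step engaging at speech
onset (zero latency, 10 ms time constant) and holding for 1 s, beyond the
stimulus window plus the window support — leaving only onset-side smear
(≈ −0.94·m). On that design, injected magnitudes {0, 0.5, 1, 2} dB are
recovered as mean trial deltas within 0.2 dB and strictly monotone. The
default cohort keeps the syllable-locked envelope; its recovered deltas
are expected to shrink by the measured ≈12%, which affects no sign-based
conclusion.

## Calibration experiments

Run on measurement-level replicates of a reduced cohort (12 subjects, 40
trials — sizes chosen to keep replicated simulation affordable while
preserving the structure):

- **Sign/CI recovery.** Each model is validated under its own generative
  process (cognitive: group effect zeroed; group: composite effects
  zeroed). With every default effect active simultaneously, each model
  omits the other's terms while group membership correlates with the
  composites, so fitted coefficients are biased for the injected ones and
  coverage of the injected value is not a meaningful target (measured
  ≈0.66–0.78). Signs are read from trial-level cluster-robust fits under
  generator defaults; CI coverage is evaluated in the linear regime
  (`clip_magnitude=False`, since the max(0,·) floor binds for ≈7% of
  subjects at μ = 1 dB and attenuates slopes) with subject-aggregated
  fits. Measured: all three signs recovered in 98% of 50 replicates;
  per-coefficient coverage 0.96/0.96/≈0.96.
- **Permutation null.** Group labels are permuted across subjects in 500
  fresh replicates and the subject-aggregated group test applied at
  α = 0.05; the empirical type-I error is ≈0.04–0.05 and the permuted
  coefficient is centered on zero.

## Numerical conventions and degenerate inputs

- Frame count: floor((N − window)/hop) + 1; recordings shorter than one
  window are rejected with the required minimum in the message.
- Inclusive boundaries: line-noise tolerance (5 Hz), tracking window
  (±25 Hz). Exclusive: stability threshold ("> 6 dB").
- A locally monotonic spectrum yields a missing tracked peak, never an
  extrapolated one; windows falling off the recording are flagged missing.
- Oscillator frequencies above sample_rate/2.5 are rejected (anti-alias
  margin beyond Nyquist); mains harmonics at or above Nyquist likewise.
- z-scoring a zero-variance task is an error naming the task; rank
  deficiency in a design is an error naming the columns.
- All randomness flows from explicit integer seeds (NumPy PCG64);
  identical configurations reproduce outputs byte for byte.

## Known limitations

- Trial-level OLS default mirrors the plain-linear-model convention and is
  anticonservative under within-subject clustering; use the cluster or
  subject-aggregated options for inference you intend to trust.
- The sustained-suppression recovery bound (±0.2 dB) does not apply to
  syllable-locked epochs, which shrink by ≈12% under the stated window
  parameters.
- Detection thresholds are tuned to a ~20 dB peak-to-floor margin; real
  recordings with poorer probe fits would need the configurable thresholds
  revisited.
- The generator's covariate distributions are stylized (normal latents,
  fixed task noise); it supports recovery testing, not epidemiological
  realism.
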