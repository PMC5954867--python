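# Methods

## The monitoring model

The monitor treats mental fatigue as a *departure of the EEG spectrum
from an alert-state reference*. Spectral power in the θ (4–7 Hz) and
α (8–11 Hz) rhythms is known to change with vigilance; rather than
tracking raw band power (which varies strongly across subjects and
electrode placements), the monitor characterizes a subject's alert
state by the mean vector and covariance matrix of their band-spectral
features and measures each new epoch's Mahalanobis distance from that
reference. The distance is unitless, subject-calibrated, and sensitive
to spectral change in either direction. The two band distances are
combined as a convex mixture D_C = σ·D(x_α) + (1 − σ)·D(x_θ).

Assumptions this rests on:

- The alert-state feature distribution is stationary over the baseline
  window and approximately elliptical (log power makes this far more
  plausible than raw power).
- Fatigue changes θ/α spectral content enough to move the feature
  vector several baseline standard deviations away.
- Artifacts are either removed by BSS or excluded by the amplitude
  rule before features are computed; scoring a contaminated epoch is
  worse than skipping it, so the monitor skips and logs such epochs.

## Pipeline stages and parameters

**Epoching** (`eegfatigue.io`). Default epoch length 2 s, no overlap.
2 s at the default 512 Hz gives ≥ 8 cycles of the lowest θ frequency
and 0.5 Hz periodogram resolution, enough for 1 Hz feature bins. Time
is 0-based seconds from record start; data are channels × samples in
μV.

**Artifact rule** (`eegfatigue.preprocessing`). A sample is an
artifact iff |amplitude| > 50 μV, *strictly*: 50.0 μV exactly is
clean. An epoch is contaminated iff any of its samples is flagged.

**BSS removal** (`eegfatigue.preprocessing`). SOBI — whitening by PCA
followed by Jacobi joint diagonalization of lagged covariance matrices
(lags 1..8) — was chosen over ICA because it is deterministic (no
random initialization) and exploits the temporal structure of EEG
rhythms; FastICA is retained as a fallback if the eigendecomposition
fails. Single-channel recordings are delay-embedded (Hankel matrix of
16 lagged copies) so the same machinery applies; reconstruction is by
anti-diagonal averaging. A component is rejected when (a) its
back-projected contribution violates the 50 μV rule, or (b) its excess
kurtosis exceeds 5 — sparse high-amplitude transients (blinks, spikes)
are strongly leptokurtic, whereas band-limited Gaussian-like EEG has
excess kurtosis near 0. In the clean limit no component is rejected
and the record passes through bit-exactly, which also gives
idempotence.

**Rhythm extraction** (`eegfatigue.features`). A dyadic DWT cannot
honor the 4–7/8–11 Hz edges (its bands at 512 Hz are 4–8, 8–16, ...),
so epochs are decomposed with a wavelet *packet* transform (db4),
depth chosen so leaves are ≤ 2 Hz wide (depth 7 at 512 Hz). Because
finite wavelet filters leak tone energy into neighboring leaves, a
two-leaf (4 Hz) guard band is kept on each side of the nominal band,
and the exact edges are then enforced by a zero-phase 4th-order
Butterworth band-pass. Narrowband zero-phase filtering of a short
epoch loses energy to edge transients under scipy's default padding,
so the filter uses generous reflect padding (up to 2 s). The residual
is defined by subtraction, making the three-component reconstruction
exact by construction.

**Features.** Log power of each band component in half-open 1 Hz bins
([4,5), [5,6), [6,7); [8,9), [9,10), [10,11)), from a boxcar
periodogram. The log stabilizes the baseline covariance; bins are
clamped below at 1e-12 before the log, so a zero signal maps to
log(1e-12) in every bin and amplitude scaling by a adds exactly
log(a²) to every above-floor bin.

**Baseline** (`eegfatigue.scoring`). Per-band sample means and shrunk
covariances C = (1 − λ)S + λ·diag(S), λ = 0.1 by default, plus a tiny
trace-scaled ridge (1e-9) so the matrix stays invertible even for
degenerate baselines (identical epochs, n < dim). The default baseline
is the first 30 artifact-free epochs of a session (60 s), or a
separate calibration recording. Means and covariances are per band:
the α and θ spectra measure different quantities, so a shared mean
would be ill-defined even though both distances enter D_C.

**σ.** Default 0.5 — with no evidence favoring either rhythm, the
combination weights them equally; σ is exposed everywhere for
sensitivity analysis.

**Thresholding** (`eegfatigue.calibration`). The ROC curve uses the
same strict-exceedance convention as the alarm (`D_C > t`), with
candidate thresholds at every distinct score plus a −∞ sentinel, so
the curve spans (0,0)–(1,1) and its trapezoid area equals the
Mann–Whitney pair statistic (ties ½). Youden selection maximizes
TPR − FPR; among ties the lowest candidate wins, and the returned
operating point is the midpoint of the gap between that candidate and
the next distinct score above it, so the threshold sits strictly
between classes when they separate. The package's fixed default
threshold is 6.0, the operating point of the original monitoring
system (reported there in μV although the distance itself is
unitless; this package treats all D values as unitless). An
alternative calibration without labels, `percentile_threshold`, places
the threshold at an upper percentile of alert-session scores; it fits
a lognormal to the scores because at percentiles like 99.9 the sample
order statistic of a few-hundred-epoch run is a very noisy tail
estimate, whereas the parametric point is stable (alert D_C is
right-skewed and well described on the log scale).

**Alarm.** Strict rule: alarm iff D_C > threshold; 6.0 exactly does
not alarm. Optional debouncing (default off, k = 1) requires k
consecutive exceedances before an event is raised — a Youden-balanced
threshold tolerates a small alert-tail exceedance rate by design, and
isolated single-epoch crossings are the expected false-alarm mode.
"Alarm" is a structured log event plus a summary counter, not audio.

## Trial-series analysis

Learning curves over repeated trials are modeled as piecewise-linear
phases: improvement during skill acquisition, a plateau, then
fatigue-driven deterioration. Each phase is a closed-form OLS line
with R² = 1 − SSE/SST (a constant series fit by a flat line has
R² defined as 1). Phase boundaries differ across metrics and studies,
so they are an input; the automatic mode scans all breakpoint
placements (≤ 3 phases by default, each ≥ 3 trials — 2-point phases
are degenerate with R² ≡ 1) for minimum total SSE, breaking ties
toward fewer phases and then earlier breakpoints. No phase-count
penalty is applied by default.

The built-in phase models are: errors 12.13 − 1.4x (trials 1–7),
3.34 − 0.13x (8–12), −5.96 + 0.62x (13–20); subjective fatigue
2.35 + 0.15x (1–9), a plateau at 3.6 (10–13), 3.15 + 0.212x (14–20).
The middle error phase is extended through trial 12 to keep the
default generator's phases contiguous. The completion-time defaults
are reconstructed from printed anchors (≈130 s at trial 1, a minimum
near 92 s at trial 14, ≈110 s by trial 20) because no usable late-phase
equation is published; completion time is capped at 300 s, the
simulator's limit.

## The synthetic-data generator

Each rhythm band is narrowband-filtered white Gaussian noise (6th-order
Butterworth, zero-phase) scaled to a target RMS — not a sinusoid —
so that band features have realistic within-band variance, which the
baseline covariance needs. Defaults: 512 Hz sampling (typical of
consumer forehead headsets and dyadic-friendly), δ/θ/α/β RMS
4/6/8/3 μV, broadband floor 2 μV, single channel labeled FP1.

Fatigue is a per-epoch drift level in [0, 1] that scales the θ- and
α-band amplitudes by 1 + direction·gain·drift with gain 0.6 and
direction −1 by default — θ/α relative power *decreases* with fatigue,
the direction the monitoring model was built around; a sign switch is
exposed because part of the vigilance literature reports the opposite,
and the Mahalanobis statistic is direction-agnostic anyway. Epochs
with drift 0 are labeled alert, all others fatigued.

Artifacts: blinks are 300 ms raised-cosine pulses peaking at
100–150 μV (placed disjointly), spikes 20 ms triangles at 80–150 μV
with random sign, line noise a continuous mains-frequency sinusoid
(default 50 Hz, 25 μV RMS). Only the >50 μV detectability criterion is
prescribed by the monitoring rule; the waveforms are this package's
choices.

What the generator does *not* emulate: non-stationary background
drift, 1/f spectral shape, electrode pops, movement artifacts
coinciding with fatigue, inter-subject variability, or any coupling
between EEG drift and trial performance. Passing tests therefore
demonstrate that the pipeline recovers the *modeled* fatigue signature
under controlled conditions, not field performance on real recordings.

## Problem sizes used in the checks

The end-to-end detection check uses two 10-minute single-channel
sessions at 512 Hz (300 epochs each; a calibration session for the
Youden threshold and a held-out session for TPR/FPR), baselines from
the first 30 epochs, and a drift step at the session midpoint. The
false-alarm check uses ten seeded pairs of a 10-minute alert
calibration run and a 2-minute monitored run. BSS checks run on 30 s
at 256 Hz. Trial-model checks use the 20-trial series above.

## Numerical choices and degenerate inputs

- Mahalanobis uses a Cholesky solve and reports the condition number
  when the covariance is not SPD.
- CSV I/O round-trips float64 exactly (`%.17g` plus `float()`
  parsing); EDF quantizes to 16 bits against the header-rounded
  physical range, so round-trip error is at most half a quantization
  step, and the written files read back identically in MNE.
- An all-zero record passes through BSS unchanged; zero-variance
  feature columns survive baseline fitting via the ridge.
- Epoch counts follow floor((N − W)/S) + 1 with trailing partial
  windows discarded; a record shorter than one epoch raises.

## Known limitations

- The BSS rejection rule (50 μV back-projection / kurtosis > 5) is a
  design decision; no universally accepted criterion exists, and on
  real data the kurtosis bound may need retuning.
- ROC labeling of fatigued epochs must be supplied (from simulation or
  a label column); the package does not infer ground truth.
- Real-time operation is per-epoch batch processing of file input;
  per-epoch cost is far below the 2 s epoch duration on a desktop CPU,
  but no hard latency guarantee is made.
- The learning-curve module fits means of trial metrics; it does not
  model subject-level random effects or test phase differences.
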