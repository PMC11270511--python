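# Methods

This note documents the models and procedures implemented in `perisacc`,
the parameters that matter, and what the synthetic data do and do not
establish.

## Task geometry and correspondences

Two fixation points sit at (±10.04, 0) dva. Around each point, four
stimulus locations form a 2×2 grid: horizontal offset ±√(5.06² − 2.53²) ≈
±4.38 dva, vertical offset ±2.53 dva, so each location is exactly 5.06 dva
from its fixation point and vertically adjacent locations are 5.06 dva
apart. Location ids are retinotopic: 1–4 around the fixated point
(1 upper-left, 2 lower-left, 3 upper-right, 4 lower-right, in screen
coordinates), 5–8 the same grid around the other point.

Two correspondences drive the cross-condition analyses:

- **remap_pairs** {5→1, 6→2, 7→3, 8→4}: a saccade between the fixation
  points translates the retinal image by 20.08 dva, so a peripheral
  location lands on the central location with the same offset relative to
  its fixation point. This is a pure translation and holds in both saccade
  directions.
- **nearest_spatiotopic** {5→3, 6→4, 7→1, 8→2}: the central location a
  peripheral stimulus is *confused with* in the absence of a saccade. For
  the inner column (5, 6) this is literally the nearest central location
  on screen (upper inner peripheral faces upper inner central across the
  screen center). We extend the map antisymmetrically to the outer column
  so that for every peripheral location the confusion target is the
  horizontal complement of the remap partner. This choice is what makes
  remapped-label and nearest-label accuracies exactly complementary on a
  horizontal-pair test set, and makes spatiotopic confusion pull the
  classifier *against* the remapped label on every trial — the mechanism
  behind below-chance control decoding. The geometric "nearest central
  location" for the outer column would coincide with the remap partner
  itself; under that reading confusion and remapping would be
  indistinguishable for half the trials, so the analysis-relevant
  antisymmetric map is used and documented here as a deliberate modeling
  decision.

## Trial schedule

A full session holds 2,400 trials in 5 blocks of 480 (224 fixation, 224
saccade — split evenly between central and peripheral stimulus placement —
and 32 control per block), randomly interleaved; oddball catch trials are
flagged every 11–20 trials on top of this structure so the printed counts
stay exact. Orientations cycle through 0–150° in 30° steps (6 values).
Trials occupy fixed 2.5 s slots on a continuous timeline. Fixation/control
trials present the stimulus 400–800 ms after trial onset; saccade trials
start the cue 200–600 ms after onset, draw a cue-to-saccade latency
uniformly from 550–850 ms, draw the SSOA from a truncated normal (mean
250 ms, SD 80 ms, support 100–400 ms) and place the stimulus at saccade
onset minus SSOA. The adaptive per-participant stimulus-delay titration of
the original task is not reproduced; the fixed SSOA distribution was chosen
so all three SSOA bins are well populated at desk scale.

## Forward model (synthetic EEG)

64 abstract channels; channels 44–59 are "occipital" (topography SD 1.0
vs 0.15 elsewhere), channels 62–63 are the reference mastoids (zero
loadings). Each retinotopic location has a unit-norm random topography,
drawn per subject (a cohort sharing one pattern set produces spurious
group-level structure). The single-trial signal model, all amplitudes in
µV:

- evoked kernel: Gaussian transient (peak 165 ms, SD 20 ms, gain 6) plus a
  sustained plateau (gain 4, rising 100–150 ms, fading out at 350 ms). The
  finite plateau makes control decoding return toward chance late in the
  epoch, matching the transient-plus-sustained shape of position
  decodability.
- peripheral stimuli evoke the unnormalized mixture
  (1 − w)·T(p) + w·T(nearest_spatiotopic(p)) with confusion weight
  w = 0.5.
- remapped component: Gaussian (peak 184 ms, SD 20 ms, gain 8) on
  T(remap_pairs(p)), added only on peripheral saccade trials with SSOA in
  (100, 200] ms.
- retinotopic trace: on saccade trials the evoked kernel is cut
  `trace_duration_ms` (default 100) after saccade offset with a 30 ms
  cosine fade; a null variant cuts at saccade onset with zero trace.
- noise: spatially correlated Gaussian (SD 7.5 per sample, compound
  symmetry ρ = 0.3), white in time.
- ocular artifact: one frontal-dominant topography carrying the
  corneoretinal potential (10 µV/dva of horizontal gaze) plus a spike
  potential (30 µV Gaussian, SD 5 ms) at every saccade and microsaccade
  onset. The spike potential is what the −20…+10 ms variance-ratio window
  actually detects; without it the criterion has almost nothing to measure
  in that window.

Gains were calibrated once, against the published real-data scale of the
analyses this generator emulates (fixation peaks ~70%, control dip below
chance, short-bin remapped peak in the high 50s), before the acceptance
checks were run, and have not been adjusted since.

The gaze trace (1000 Hz) uses a raised-cosine saccade velocity profile
(default duration 45 ms, so a 20.08 dva saccade peaks near 890 dva/s, on
the human main sequence), smoothed drift (SD 0.15 dva), white positional
noise (SD 0.02 dva), optional microsaccades (<1 dva, 0.1 Hz) and optional
blinks (validity flag False, NaN samples; off by default in the pipeline).

## Preprocessing

Signal conditioning: resample to 256 Hz if needed (input must be ≥160 Hz),
re-reference to the mastoid mean, 50 Hz FIR notch, 0.1–80 Hz zero-phase
FIR bandpass (Hamming window; parameters recorded in a provenance dict).

Saccade detection is the Engbert–Kliegl velocity-threshold algorithm: the
5-sample moving-window differentiator, per-axis median-based SDs
σ = √(median(v²) − median(v)²), an elliptic threshold at λ = 5 SDs
sustained ≥15 ms, and a <50 ms merge rule keeping the first event. Blink
samples are interpolated for differentiation but excluded (with a ±2-sample
guard) from threshold estimation and candidate membership. The low
threshold intentionally catches microsaccades; task saccades are those
exceeding 15 dva (strict).

Ocular components: the decomposition is pluggable; the pipeline default is
PCA from the channel covariance (deterministic, and rank-1 ocular sources
are isolated essentially perfectly in this generator). A component is
rejected when its mean variance in −20…+10 ms windows around saccade
onsets exceeds its mean variance in fixation windows by more than 10%
(ratio > 1.10, strict). Fixation windows include both pre-stimulus and
(on no-saccade trials) post-stimulus segments so stimulus-evoked
components see comparable variance in both window classes and are not
mistaken for ocular ones.

Trial gating applies, in precedence order: no valid (>15 dva) saccade on
saccade trials; stimulus still on screen at saccade landing; landing >2.5
dva from the saccade target; gaze >2.5 dva from the fixated point during
stimulus presentation; per-epoch peak-to-peak amplitude >150 µV. The
amplitude gate is a deliberately simple stand-in for subspace-
reconstruction artifact repair. Exactly one reason is recorded per trial.

Epoching: −200…+500 ms around the event at 256 Hz. Sample-grid convention:
offsets ceil(w₀·fs)…floor(w₁·fs) inclusive from the event sample
round(t·fs) — 180 samples for the default window, event sample at t = 0.
Baseline: per trial and channel, the mean over −100 ≤ t < 0 (25 samples).
Saccade-locked re-epochs subtract the trial's *pre-stimulus* baseline
instead, since the default window would fall on evoked activity.

## Decoding

Features are the 64 channel amplitudes at one timepoint. Pairwise LDA uses
the pooled class-centered covariance with Ledoit–Wolf analytic shrinkage
and equal class priors; the estimator is vectorized over timepoints and
checked against scikit-learn's `solver="lsqr", shrinkage="auto"` LDA.
Accuracy is always the unweighted mean of per-class accuracies, averaged
within pair → over pairs → over left/right fixation → over subjects (the
recorded averaging order). Fixation decoding uses stratified fivefold CV
per side and pair. The peak training timepoint is the argmax of the
pair-averaged curve in 0–500 ms, ties to the earliest sample, per subject.
Cross-condition tests use peak-trained banks; remapping analyses are
restricted to the horizontal pairs (1v3, 2v4), where control decoding is
below chance and the remapped/nearest labelings are complementary. SSOA
bins: Short (100, 200], Medium (200, 300], Long (300, 400] (half-open, so
a 200 ms SSOA is Short), and 26 sliding 100 ms bins stepped by 10 ms from
(300, 400] down to (50, 150] (centers 350→100 ms). Central saccade trials
(Short Bin) are decoded at corresponding timepoints — the diagonal of the
temporal-generalization matrix — over all six pairs. The Haufe transform
(pattern = Σw, unit-normalized) converts weights to interpretable
topographies.

## Inference

One-sample JZS Bayes factors per timepoint across subjects: H₁ puts a
Cauchy prior with scale r = √2/2 ≈ 0.707 on the standardized effect size;
the null value is 0.5 for accuracies and 0 for saccade-minus-control
differences. The default two-sided prior is integrated in its exact
inverse-gamma scale-mixture form by adaptive tanh-sinh quadrature
(rtol 1e-8) — numerically stable for arbitrarily large |t| — and verified
against a dense trapezoid integration over the effect size to ~1e-5
relative error; one-sided (half-Cauchy) variants integrate the
noncentral-t density directly and are provided for sensitivity analyses.
Evidence categories use strict thresholds: BF > 3 substantial for H₁,
BF < 1/3 substantial for H₀, otherwise inconclusive; the sliding-bin
difference matrix is masked at BF > 10. Zero-variance samples return ±∞/0
with a logged flag. No smoothing or correction is applied across
timepoints.

Two derived summaries: a "remapping detected" flag — a *sustained*
cluster of substantial above-chance evidence in the Short Bin, defined as
at least 3 consecutive timepoints (~12 ms at 256 Hz) with BF > 3 inside
120–450 ms post-stimulus, the window in which a remapped representation
can physically occur (after the feedforward response, away from the epoch
edge). The run-length and window were calibrated once against a
no-remapping null simulation, where isolated one- to two-sample BF
excursions occur by chance; the injected effect produces runs of 4–5
samples at 180–195 ms. And
the retinotopic-trace persistence — from the saccade-offset-locked central
analysis, the end of the last run of group accuracy at or above the
half-plateau level (midway between the pre-offset plateau and chance)
among runs present shortly after the offset. The half-plateau crossing is
used rather than the BF series because at 10 subjects the BF run can
fragment on single noisy samples while the crossing is stable.

## Desk-scale defaults and runtime

The default run is 10 synthetic subjects × 1 block (480 trials), chosen so
a full effect-plus-null comparison completes in minutes on one CPU; a full
2,400-trial session is available via `blocks_per_session=5`. At this scale
one subject contributes ~112 fixation/saccade trials per condition and
~28 Short-Bin peripheral trials, so single-subject generalization curves
are noisy and all claims are made at the group level.

## What passing tests show — and do not show

The generator emulates the *structure* the analyses assume: retinotopic
topographies, a confusion mixture, an SSOA-gated remapped component, a
finite retinotopic trace, and ocular artifacts time-locked to real gaze
behavior. Passing recovery tests show the pipeline detects exactly the
effects injected and nothing under the null. They do not show that real
EEG satisfies these assumptions: real topographies are spatially smooth
and correlated across nearby locations, noise is temporally autocorrelated
and nonstationary, ocular artifacts are not rank-1, ICA on real data is
imperfect, and real effect sizes and latencies vary across subjects.
Numbers produced here at desk scale (e.g. sub-0.35 control dips) are
sharper than their real-data counterparts because the synthetic confusion
is exact.

## Known limitations

- The ICA estimation itself is out of scope; a PCA stands in as the
  default decomposition and is sufficient for the rank-1 synthetic
  artifacts, not for real data.
- Subspace-reconstruction cleaning is replaced by the peak-to-peak gate.
- No EDF export (no EDF writer among the package's dependencies); the
  epoch container (npy + JSON sidecar + CSV metadata) and CSV interfaces
  are the on-disk formats.
- Temporal-generalization analyses beyond the diagonal, nonlinear
  classifiers and channel-subset searchlights are out of scope.
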