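# Methods

## The decoding problem

A selective-sensation BCI presents identical vibrotactile stimulation
to both wrists; the user attends to one side. Covert attention
modulates somatosensory rhythms: band power in alpha (8–13 Hz) and/or
beta (13–26 Hz) drops over the hemisphere contralateral to the attended
side (event-related desynchronization, ERD). The decoding task is
two-class single-trial classification, left vs right attention, from
multichannel scalp EEG epochs. Everything in this package operates on
epoched sessions: a `trials × channels × samples` tensor at 250 Hz with
per-trial labels and run indices.

## Synthetic session generator

No public recordings exist for this paradigm, so the generator is a
first-class, tested component that defines the study conditions:

- **Paradigm** (defaults): 250 Hz, 8 s trials, cue at 3 s, task window
  4–7 s, baseline 1–3 s, 4 runs × 40 trials, balanced classes within
  every run (80 per class per session).
- **Sources**: two oscillatory sources, one per hemisphere, realized as
  white noise band-pass filtered to the effect band (default 10–13 Hz,
  4th-order Butterworth, zero-phase). Filtering uses 1 s of padding
  cropped afterwards so source band power is stationary across the
  epoch — without this, filter warm-up transients at the epoch edges
  masquerade as spectral events and miscalibrate the ERSP bootstrap.
- **Mixing**: fixed linear mixing to channels with Gaussian spatial
  profiles (σ = 2 channel indices) centered on two source channels
  (defaults: indices n/4 and 3n/4, synthetic analogs of C3/C4). This is
  the minimal forward structure under which CSP is the matched decoder.
- **ERD**: multiplicative amplitude scaling of the *contralateral*
  source by (1 − `erd_depth`) inside the task window, with 100 ms
  cosine ramps to avoid spectral splatter. `erd_depth = 0.6` is the
  default "strong but not trivial" contrast used by the recovery suite;
  `erd_depth = 0` produces a null session in which labels are provably
  exchangeable. The effect exists only inside the task window, so the
  pre-cue baseline never carries class information.
- **Noise**: independent 1/f^β noise per channel (β = 1), unit
  variance, spectrally shaped in the Fourier domain (circularly
  stationary). `snr_scale` (default 1) sets source amplitude relative
  to the noise floor. No real-data ERD effect sizes are published for
  this paradigm, so the defaults are chosen for test discriminability,
  not fidelity to any subject.
- **Randomness**: one integer seed expands through `SeedSequence` spawn
  keys into independent per-run label streams and per-trial data
  streams, so generation is bit-reproducible and extending a session
  with more runs never changes earlier trials.
- An optional `amplitude_drift` applies a slow linear gain across the
  session to stress the online adaptation; it defaults to 0.

What the generator does *not* emulate: head-model volume conduction and
electrode geometry, eye/muscle artifacts, line noise, inter-trial
timing jitter, feedback-induced non-stationarity, or any steady-state
response to the stimulation itself. Passing tests therefore demonstrate
correctness of the algorithms under a known forward model, not
performance on real EEG.

## Preprocessing

4th-order Butterworth band-pass, applied zero-phase
(forward–backward) to the whole 8 s epoch *before* window extraction so
IIR edge transients fall outside the analysis window; a `causal=True`
switch gives a single forward pass for strict-causality studies. Band
presets: lower_alpha 8–10, upper_alpha 10–13, alpha 8–13, lower_beta
13–20, upper_beta 20–26, beta 13–26, broad 8–26 Hz. Windows are
half-open `[start, end)` with boundary indices `round(t·fs)`, making
lengths exact (4–7 s → 750 samples) and nested extractions composable.
Zero-phase filtering was chosen because all analysis here is post hoc
on complete epochs; the anticausal smear of task-window structure into
the baseline was measured at ~5·10⁻⁷ RMS relative to signal —
negligible.

## CSP

Per-trial covariance is trace-normalized, `C = XXᵀ/tr(XXᵀ)` (a warning
is raised when samples ≤ channels). Class means are arithmetic
averages. The fit eigendecomposes the symmetrized composite
`Cc = C1 + C2`, errors on genuine rank deficiency (naming the rank),
ridge-regularizes with `1e-10·tr(Cc)/n·I` only when the condition
number exceeds 1e12, whitens with `P = Λ^{-1/2}Uᵀ`, diagonalizes the
whitened class-1 covariance, and returns `W = BᵀP` with rows sorted by
descending class-1 eigenvalue. Conventions that the underlying algebra
leaves free and that are fixed here for determinism: eigenvector sign
(largest-magnitude coefficient of each filter made positive) and tie
order (eigendecomposition order). Patterns are the columns of the
pseudo-inverse of W. Features are natural-log variances (population
form, denominator N) of the first and last `n_pairs = 3` projected
components, 6 per trial. An equivalent fast path computes the same
features from cached *centered* per-trial covariances as
`diag(W R Wᵀ)`; the test suite asserts bit-level agreement between the
two routes, and CSP itself is checked against scipy's generalized
eigensolver (`C1 v = λ (C1+C2) v`) on random SPD instances.

## LDA

Closed-form Fisher discriminant with pooled within-class covariance
(unbiased, denominator n−2) and equal priors — the paradigm is
balanced by design. `w = S_p⁻¹(μ₂−μ₁)`, `b = −w·(μ₁+μ₂)/2`; score > 0
predicts the second class ("right"), an exact zero ties to the first
("left") — a measure-zero event made deterministic. A diagonal ridge
`1e-8·mean(diag)` is added only when ill-conditioned. Predictions are
cross-checked against scikit-learn's LDA with explicit equal priors.

## Cross-validation and the chance band

The canonical protocol: 5 repeats of a random 5-fold partition,
class-stratified so no training fold degenerates to one class; CSP and
LDA are refit inside every fold (fold indices are stored on the report
and tested for disjointness). The grid search evaluates the mean of the
25 accuracies over 7 bands × 10 post-cue windows (1–2 … 4–5 s, mapped
to trial time by adding the cue onset); ties break toward the longer
window, then the lower band. The baseline control runs the identical
procedure on the 1–3 s pre-cue window with the same partitions and
compares via a two-sided paired t-test (zero-variance differences are
guarded: identical vectors → p = 1, constant shift → p = 0).

Two chance bands are provided and used for different claims.
`chance_band(n)` is the exact binomial 95% band for n independent
decisions; across *ensembles* of null sessions the CV mean leaves this
band rarely (≤10% observed ~3%), which is the calibration property the
suite asserts. For a *single* session, fold accuracies are strongly
correlated (folds share training data and the classifier's noise-fit
direction, which also produces the well-known slight below-chance bias
of CV on null data), so the session-to-session spread of the CV mean
exceeds the independent-binomial width; `cv_chance_band(n, k)` uses the
binomial band for one test partition (n/k decisions) as the loose bound
appropriate to a single-session at-chance check. Label-permutation
testing on generated sessions confirmed that apparent below-chance
baseline accuracies are tail draws of exchangeable data, not leakage.

## Online adaptation

Trials are replayed chronologically. Run 1 only calibrates. Before
predicting trial k of run r ≥ 2, the full pipeline is refit on all
trials of run r−1 plus trials 1..k−1 of run r — training size
`trials_per_run + (k−1)` — and retraining continues after every trial
including the last of a run. The procedure involves no randomness, so
it takes no seed; causality (past predictions invariant to future-trial
mutation) is asserted structurally in the tests. Subject reaction to
feedback is not modeled; the generator's drift knob exists to stress
adaptation when wanted.

## ERSP and the bootstrap mask

Per channel, complex convolution with Hanning-tapered sinusoid wavelets
sampled every 200 ms; the cycle count interpolates linearly from 3 at
the lowest to 8 at the highest analysis frequency (short wavelets →
time resolution at low f; more cycles → frequency resolution at high
f). The time grid is restricted to instants where the longest wavelet
fits entirely inside the epoch, so convolution edge effects never enter
the map. Power is trial-averaged and expressed as
`10·log₁₀(P(t,f)/P̄_baseline(f))` (ratio form available), which makes
the map invariant to global amplitude scaling.

Significance: a surrogate bootstrap per frequency. Each of `n_boot`
resamples draws trials with replacement and, per drawn trial, one
random baseline time point; the resulting surrogate trial-mean powers
form the null distribution, and observed cells outside its central
1−α quantile band are flagged (two-sided, α = 0.01 default). The
default `n_boot = 1000` reflects that a 0.005 tail quantile needs far
more than 1/0.005 resamples to be stable. Measured type-I rate on null
sessions: ~0.015 at α = 0.01 (within [α/2, 2α]); the mild residual
inflation is the usual finite-n percentile-bootstrap effect. Trial-level
resampling is a documented choice — the resampling unit is not
identifiable from published descriptions of the tool, so calibration by
property replaces bit-compatibility with any specific toolbox.

## I/O and reproducibility

Sessions round-trip through a single `.npz` container with an embedded
JSON metadata record (format tag, sampling rate, channel names,
generating config and seed); malformed or truncated files raise
`SessionIOError`, not a crash. Configurations are flat key-value
YAML/JSON mirroring the paradigm/effect fields; unknown keys are
rejected. The `workflow` entry point chains
simulate → CV/baseline → grid → online → ERSP, writes CSV/JSON/array
outputs plus a manifest with the package version, config hash and named
per-stage seeds; rerunning the same config reproduces every output byte
for byte. All stage seeds derive from one top-level seed via named
substreams and stay below 2³¹.

## Problem sizes used by the test and acceptance suites

Full-size checks use the default 160-trial, 22-channel session (62
channels are supported; CSP is channel-count-agnostic, and 22 keeps the
covariance algebra comfortably overdetermined at 750 task-window
samples). Structural and property tests use 24-trial, 8-channel
sessions. ERSP calibration uses 40-trial single-run sessions, 10
frequencies (8–26 Hz), 50 Monte-Carlo replicates. These sizes are the
package's own test design: large enough that every statistical claim is
sharp, small enough that the whole suite runs in about a minute.

## Known limitations

- The generator's linear instantaneous mixing and stationary 1/f noise
  are idealizations; real EEG adds volume-conducted artifacts,
  non-stationarity and inter-subject variability that no test here
  covers.
- Two-class CSP only; no multi-class extension, shrinkage/analytic
  regularized CSP, or channel selection.
- LDA without shrinkage or probability calibration.
- No multiple-comparison correction across the 70 grid cells (the grid
  is exploratory; its selection is validated by the paired improvement
  test, not by per-cell inference).
- The ERSP bootstrap is calibrated by property (type-I rate), not
  bit-compatible with any particular EEG toolbox's variant.
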