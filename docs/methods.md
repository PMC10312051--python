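# Methods

This note documents the models and procedures implemented in `oculodyn`,
the assumptions behind them, the defaults that matter, and what the
synthetic-data generator does and does not emulate.

## Scope and data model

The package analyzes concurrent binocular eye-tracking data recorded while
a participant performs a speech-in-noise task under two listening-load
conditions (high load, HL = speech at the individual 50%-correct SNR; low
load, LL = that SNR + 10 dB). Two ocular signals are extracted from the
same recording:

* **pupil dilation (PD)** — an index of arousal with tonic (baseline) and
  phasic (sentence-evoked) components;
* **microsaccade (MS) rate** — small fixational saccades (~1–2 events/s)
  whose incidence transiently drops when attentional demand rises.

Continuous recordings (`GazeRecording`: time, per-eye x/y/pupil, validity
masks, event markers; 1000 Hz by default) are cut into fixed peristimulus
epochs of [−2, 5.5) s around each trial's noise onset. Epoch windows are
half-open in samples so every epoch has exactly 7500 samples at 1000 Hz;
onsets falling between samples are aligned to the nearest sample.

## Pupil preprocessing chain

Order is fixed and matches the module composition tested against a
straight-line oracle:

1. **Fixation/blink masking.** Samples of the analyzed eye (left by
   default) farther than 100 px (strict `>`) from the fixation cross, or
   already invalid (blinks/closures), become missing.
2. **Participant exclusion.** A participant with a strictly greater than
   50% overall missing fraction is excluded.
3. **Epoch rejection.** Epochs with strictly more than 50% missing samples
   are discarded.
4. **Interpolation.** Remaining gaps are linearly interpolated between
   nearest valid neighbors; edge gaps hold the nearest valid value
   (no extrapolation).
5. **Outlier-trial removal.** Per time point, the mean and SD across the
   surviving trials of the trial's own condition (computed after
   interpolation, before z-scoring) define the reference; a trial is
   removed when ≥ 10% of its samples deviate by strictly more than 3 SD.
   Whether this rule should run on raw or baseline-corrected data is not
   externally fixed; the raw-interpolated reading is the only one
   computable trial-by-trial and is used throughout.
6. **z-scoring.** One mean and SD pooled over all retained samples of both
   conditions per participant (not per time point); the pooled transformed
   data has mean 0, SD 1.
7. **Baseline correction** (optional, on by default for phasic analyses):
   per-trial subtraction of the mean over [−0.2, 0) s.
8. **Averaging.** Trial-mean per condition per participant, then an
   unweighted mean across participants.

Summary measures: peak latency/amplitude (argmax in a search window, ties
to the earliest sample), the load effect (mean HL−LL over [2, 5] s), and a
blink-incidence series (fraction of trials missing at each time point,
computed before interpolation).

## Microsaccade detection

Velocity is estimated per eye and axis with the 5-sample moving-window
stencil `v[n] = (x[n+2] + x[n+1] − x[n−1] − x[n−2]) / (6Δt)` (exact on
linear motion); velocity samples whose window overlaps missing data are
masked. The threshold scale is the median-based SD
`σ = sqrt(median(v²) − median(v)²)` per axis, per eye, over the
participant's whole block — robust to the saccades themselves. Events must

1. exceed the elliptical threshold
   `(vx/(λσx))² + (vy/(λσy))² > 1` with λ = 6;
2. last 5–100 ms (runs adjacent to masked samples are discarded because
   their true extent is unknown);
3. appear in both eyes with onset disparity strictly below 10 ms (greedy
   chronological pairing; binocular onset = earlier monocular onset,
   duration = longer monocular duration, unpaired candidates dropped);
4. follow the previous retained event by strictly more than 50 ms
   (earlier event wins).

Because the threshold is relative (λσ), detection is invariant to a global
rescaling of gaze units; gaze units are therefore abstract throughout. A
recording with no gaze motion at all yields an empty event list rather
than a degenerate-scale error.

## Rate estimation

Detected events become unit pulses on the epoch axis. The raw rate is the
pulse sum across trials divided by the trial count and multiplied by the
sampling rate (events/s). It is smoothed with the causal spike-rate kernel

    ω(τ) = α² τ e^(−ατ),   τ ≥ 0

with characteristic time 1/α = 150 ms (α ≈ 6.667 s⁻¹). The literature this
kernel comes from quotes "α = 150 ms"; since ατ must be dimensionless the
150 ms figure is read as the kernel's characteristic (peak) time, exposed
as a configurable `alpha`. The discrete kernel is renormalized so
Σω·dt = 1 (default support 18/α truncates ~3·10⁻⁷ of the mass; supports
truncating more than 10⁻⁶ are rejected). The kernel peaks at τ = 1/α with
height α/e ≈ 2.4525 s⁻¹; after convolution the time axis is shifted
earlier by the peak so the response to a pulse at t₀ peaks at t₀. The
shift is exact for the peak but cannot undo causal smearing: a sharp rate
*edge* still bleeds ~0.3–0.5 s forward (see Limitations).

An optional repair stage handles a systematic pre-onset recording dropout
([−0.3, 0) s): per trial, that window of the pulse train is replaced by
the [−0.6, −0.3) s window of a uniformly drawn other trial of the same
participant (seeded).

## Bootstrap inference

Per participant, a condition-difference trace (HL−LL) is formed; the
across-participant mean trace is bootstrapped by resampling participants
with replacement (1000 iterations). A time point is significant when the
fraction of iteration means above zero, or below zero, strictly exceeds
0.99 — two one-sided 1% tests, a nominal two-sided level of ~2%. Iteration
means of exactly zero count in neither tail. `criterion=0.995` gives a
strict two-sided 1%. No correction across time points is applied (matching
the emulated analysis); isolated spurious runs are therefore expected, and
interval extraction supports a minimum-length filter. Monte-Carlo
calibration (31 participants, 200 points, 50 replicates) puts the null
pointwise significance rate near 2–3%.

## Adaptive staircase

One-up-one-down SNR track for the 50%-correct speech-reception threshold:
start at 20 dB; correct → down, incorrect → up, by the step in force
(12 dB, then 8, 5, and a 2 dB floor). A reversal is attributed to the
trial whose induced direction differs from the previously established
direction (the first trial has no direction); the step drops to the next
schedule entry immediately after each reversal. The run ends at 7
reversals or 25 trials, whichever is first; the threshold is the mean SNR
of the final 4 reversal SNRs, and is an explicit `None` when fewer than 4
reversals occurred (a repository decision — the emulated procedure does
not state the behavior). SNR is unclamped by default; an optional clamp
exists. The simulated observer is logistic:
`p = γ + (1 − γ − λℓ)·logistic((snr − θ)/s)` with guess rate γ = 1/48 (48
color–number response alternatives) and lapse rate λℓ = 0 by default.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions used everywhere (tests, acceptance, examples).

* **Trial timing**: 2 s pre-roll, 0.5 s noise-only lead-in, sentence from
  0.5 to 2.6 s, silence to 5.5 s, 0.1 s tail; 30 trials per condition,
  31 participants, 1000 Hz.
* **Gaze**: AR(1) drift (step SD 0.002 gaze-units/sample, weak mean
  reversion) plus ballistic microsaccades with a raised-cosine velocity
  profile (smooth, zero endpoint velocity; peak velocity 2A/d for
  amplitude A and duration d). Events come from an inhomogeneous Poisson
  process (base 1.5 events/s — the middle of the physiological 1–2 range —
  times a per-condition modulation profile) thinned by a 100 ms refractory
  gap, which keeps ground truth recoverable under the >50 ms inter-event
  rule. Amplitudes 0.2–1.0 units, durations 8–30 ms, both uniform;
  directions are biased back toward fixation so gaze stays bounded. The
  right-eye copy is delayed by a uniform [0, 5] ms disparity, comfortably
  inside the 10 ms pairing window. Injected events therefore always
  satisfy the detector's admission rules, making recall a fair test.
* **Pupil**: participant baseline (SD 0.5) + condition tonic offset
  (HL 0.3, LL 0.0) + a gamma-shaped phasic bump
  `u^a e^{a(1−u)}`, `u = (t − t_on)/(t_peak − t_on)`, shape a = 8, rising
  from sentence onset and peaking after sentence offset (HL: amplitude
  0.6, peak 3.1 s; LL: 0.45, 2.8 s) + AR(1) noise (SD 0.25, correlation
  time 0.3 s, emulating slow hippus-like fluctuations).
* **Blinks**: Poisson at 2/min within trials (participants are implicitly
  resting their eyes between trials), 100–300 ms, invalid in both eyes and
  the pupil channel.
* **Between-participant variability**: tonic offset jitter (SD 0.1),
  multiplicative MS base-rate jitter (SD 0.15), phasic latency jitter
  (SD 0.1 s), pupil baseline spread.
* **Demo modulation**: the default demonstration programs a high-load MS
  rate dip of 50% over [1.5, 2.8] s. The dip edges are raised-cosine ramps
  of 0.3 s *inside* that window rather than hard steps: physiological rate
  modulations are smooth, and with step edges the causal kernel's tail
  keeps the smoothed difference significant for several hundred
  milliseconds past the true offset, which misrepresents where the effect
  ends. With smooth edges the significance mask brackets the programmed
  window to within ~0.1–0.2 s at study power.

What the generator does **not** emulate: saccadic main-sequence
amplitude–velocity coupling beyond the 2A/d profile, drift/tremor spectra,
pupil foreshortening, luminance responses, gaze-dependent pupil artifacts,
overshoots, or any audio. Passing tests therefore certify the *pipeline
mechanics* (detection criteria, normalizations, inference calibration,
recovery of programmed effects at realistic SNRs), not robustness to every
artifact of real recordings.

## Numerical choices and degenerate inputs

* Strict/inclusive boundaries exactly as the rules read: ">50%", ">3 SD",
  ">100 px", "<10 ms", ">50 ms" strict; "10% or more" inclusive; exactly
  50% missing retains, exactly 100 px retains, exactly 10 ms does not pair.
* Median-based SD at or below 1e−12 is an error (the threshold would be
  meaningless); z-scoring a constant participant is an error; bootstrap
  needs ≥ 2 participants; pre-onset patching needs ≥ 2 trials.
* Peak picking ties resolve to the earliest sample; the IMI rule keeps the
  earlier event; pairing is greedy chronological (deterministic and
  order-independent for disjoint events).
* All randomness flows from integer seeds through NumPy `SeedSequence`
  spawning; identical seeds give identical datasets, masks, and
  byte-identical pipeline CSVs.

## Problem sizes

Default analyses use the study scale: 31 participants × 2 × 30 trials of
7.6 s at 1000 Hz. A full pipeline run completes in well under a minute on
one CPU. Detector validation uses 80–100 five-second fixation trials
(500+ injected events); bootstrap calibration uses 50 replicates of a
31 × 200 null; staircase recovery uses 500 tracks. Replicated pipeline
checks (5 seeds) are used for the stochastic recovery quantities (peak
latency, mask localization), which tests estimator accuracy rather than a
single noisy realization.

## Known limitations

* The causal kernel's peak-shift correction aligns pulse responses but not
  edges; onset/offset estimates of rate effects carry a one-sided bias of
  up to a few hundred milliseconds for abrupt changes.
* The two one-sided 1% bootstrap criteria give a nominal ~2% two-sided
  level, and no multiple-comparison correction is applied across time
  points; significance masks are descriptive, as in the emulated analysis.
* The pupil outlier rule's reference trace includes the trial being
  evaluated; with very few trials per condition the rule is conservative.
* ASC support covers the text dialect described in the README, not binary
  EDF files or tracker-firmware event lines (those lines are skipped and
  counted).
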