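"""Synthetic binocular eye-tracking experiments with known ground truth.

The generator emulates a speech-in-noise listening experiment recorded with
a 1000 Hz binocular eye tracker: each trial has 0.5 s of noise-only lead-in,
a ~2.1 s sentence, and a 3 s silent tail, preceded by a 2 s pre-roll so the
full analysis epoch [-2, 5.5] s is covered.  Per trial it produces

* fixational gaze: bounded random-walk (AR(1)) drift plus ballistic
  microsaccades with a raised-cosine velocity profile, injected from an
  inhomogeneous Poisson process (physiological baseline 1-2 events/s) with
  a refractory gap, near-simultaneously in both eyes (<= 5 ms disparity);
* blinks as invalid spans in both eyes and the pupil channel;
* a pupil trace: participant baseline + condition tonic offset + a
  gamma-shaped phasic bump (parameterized peak amplitude and latency) +
  slow autocorrelated noise;

and records every injected event, so detector recall/precision and
pipeline recovery can be scored against ground truth.  A logistic
psychometric observer supplies responses for staircase simulations.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .io_eyetrack import GazeRecording

RateProfile = Callable[[np.ndarray], np.ndarray]


def flat_profile(t: np.ndarray) -> np.ndarray:
    return np.ones_like(np.asarray(t, dtype=float))


def dip_profile(start: float, end: float, depth: float,
                ramp_s: float = 0.0) -> RateProfile:
    """Multiplicative rate dip reaching ``1 - depth`` inside [start, end).

    With ``ramp_s > 0`` the dip edges are raised-cosine ramps of that
    length *inside* the window (physiological rate modulations are smooth);
    with ``ramp_s = 0`` the dip is a hard step.
    """
    if ramp_s < 0 or 2 * ramp_s > (end - start):
        raise ValueError("ramps must be nonnegative and fit inside the window")

    def profile(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        d = np.zeros_like(t)
        inside = (t >= start) & (t < end)
        d[inside] = depth
        if ramp_s > 0:
            up = inside & (t < start + ramp_s)
            down = inside & (t >= end - ramp_s)
            d[up] = depth * 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp_s))
            d[down] = depth * 0.5 * (1 - np.cos(np.pi * (end - t[down]) / ramp_s))
        return 1.0 - d
    return profile


@dataclasses.dataclass
class TrialLayout:
    """Within-trial timing (s, relative to noise onset)."""

    pre_roll: float = -2.0
    noise_onset: float = 0.0
    sentence_onset: float = 0.5
    sentence_offset: float = 2.6
    trial_end: float = 5.5
    tail: float = 0.1

    def __post_init__(self) -> None:
        if self.pre_roll > -2.0:
            raise ValueError("pre-roll must extend to at least -2 s")
        if self.trial_end < 5.5:
            raise ValueError("trial must extend to at least 5.5 s")
        if not self.pre_roll < self.noise_onset < self.sentence_onset < \
                self.sentence_offset < self.trial_end:
            raise ValueError("trial landmarks must be ordered")

    @property
    def start(self) -> float:
        return self.pre_roll

    @property
    def end(self) -> float:
        return self.trial_end + self.tail

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclasses.dataclass
class SimConfig:
    """Study conditions of the synthetic experiment.

    Defaults mirror the emulated study: 1000 Hz sampling, 30 trials per
    load condition, 31 participants, a physiological microsaccade baseline
    of 1.5 events/s, and per-condition pupil effects (tonic offset and a
    phasic bump peaking shortly after sentence offset, later/larger under
    high load).  Gaze units are abstract: the detector threshold is
    relative, so units cancel.
    """

    sampling_rate: float = 1000.0
    trial_layout: TrialLayout = dataclasses.field(default_factory=TrialLayout)
    n_trials_per_condition: int = 30
    n_participants: int = 31

    # fixational gaze
    drift_sd: float = 0.002              # gaze-units per sample
    drift_reversion: float = 0.002       # AR(1) pull toward fixation
    ms_base_rate: float = 1.5            # events/s, physiological 1-2 Hz
    ms_rate_profile: Mapping[str, RateProfile] | None = None
    ms_amplitude_range: tuple[float, float] = (0.2, 1.0)
    ms_duration_range_ms: tuple[float, float] = (8.0, 30.0)
    refractory_ms: float = 100.0
    max_disparity_ms: float = 5.0        # injected binocular onset disparity

    # blinks
    blink_rate_per_min: float = 2.0
    blink_duration_range_ms: tuple[float, float] = (100.0, 300.0)

    # pupil
    pupil_tonic: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"HL": 0.3, "LL": 0.0})
    pupil_phasic_amp: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"HL": 0.6, "LL": 0.45})
    pupil_phasic_peak_latency: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"HL": 3.1, "LL": 2.8})
    pupil_phasic_shape: float = 8.0
    noise_sd: float = 0.25
    noise_tau_s: float = 0.3             # AR(1) correlation time of pupil noise

    # between-participant variability
    tonic_jitter_sd: float = 0.1
    rate_jitter_sd: float = 0.15         # multiplicative, on ms_base_rate
    latency_jitter_sd: float = 0.1
    baseline_sd: float = 0.5             # participant pupil baseline spread

    # recording artifacts
    preonset_dropout_s: float = 0.0      # masked span before each onset

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        lo, hi = self.ms_duration_range_ms
        if not (5.0 <= lo <= hi <= 100.0):
            raise ValueError("microsaccade durations must lie within [5, 100] ms")
        if self.refractory_ms <= 50.0:
            raise ValueError("refractory must exceed the 50 ms inter-event rule")
        if self.max_disparity_ms >= 10.0:
            raise ValueError("injected disparity must stay inside the 10 ms pairing window")
        for name in ("drift_sd", "ms_base_rate", "blink_rate_per_min", "noise_sd",
                     "tonic_jitter_sd", "rate_jitter_sd", "latency_jitter_sd",
                     "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_trials_per_condition < 0 or self.n_participants < 0:
            raise ValueError("counts must be nonnegative")
        lay = self.trial_layout
        for cond, tp in self.pupil_phasic_peak_latency.items():
            if not lay.sentence_onset < tp < lay.end:
                raise ValueError(
                    f"phasic peak latency {tp} s for {cond!r} outside the trial window")

    @property
    def conditions(self) -> list[str]:
        return list(self.pupil_tonic)

    def profile_for(self, condition: str) -> RateProfile:
        if self.ms_rate_profile is None:
            return flat_profile
        return self.ms_rate_profile.get(condition, flat_profile)


@dataclasses.dataclass
class InjectedMS:
    participant: str
    trial: int
    onset: float          # s, on the recording's time axis
    onset_rel: float      # s, relative to trial onset
    duration_ms: float
    amplitude: float
    angle: float
    condition: str = ""


@dataclasses.dataclass
class BlinkInterval:
    participant: str
    trial: int
    start: float
    end: float


@dataclasses.dataclass
class GroundTruth:
    injected_ms: list[InjectedMS] = dataclasses.field(default_factory=list)
    blink_intervals: list[BlinkInterval] = dataclasses.field(default_factory=list)
    programmed_pd: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    time: np.ndarray | None = None       # trial-relative axis of programmed_pd

    def ms_table(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(e) for e in self.injected_ms])


@dataclasses.dataclass
class ParticipantRecording:
    participant: str
    recording: GazeRecording
    trials: pd.DataFrame      # columns: trial, condition, onset_s


@dataclasses.dataclass
class ExperimentData:
    participants: list[ParticipantRecording]
    ground_truth: GroundTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# observer
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ObserverModel:
    """Logistic psychometric observer for the staircase.

    ``p(correct) = guess + (1 - guess - lapse) * logistic((snr - threshold)/slope)``.
    The guess rate defaults to 1/48 (48 color-number response alternatives).
    """

    threshold_db: float
    slope_db: float
    guess_rate: float = 1.0 / 48.0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.guess_rate < 1.0:
            raise ValueError("guess_rate must lie in [0, 1)")
        if not 0.0 <= self.lapse_rate < 1.0 - self.guess_rate:
            raise ValueError("lapse_rate must lie in [0, 1 - guess_rate)")
        if self.slope_db <= 0:
            raise ValueError("slope must be positive")

    def p_correct(self, snr_db: float) -> float:
        core = expit((np.asarray(snr_db, dtype=float) - self.threshold_db) / self.slope_db)
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * core

    def snr_at(self, p: float) -> float:
        """SNR at which p(correct) = p, by analytic inversion."""
        core = (p - self.guess_rate) / (1.0 - self.guess_rate - self.lapse_rate)
        if not 0.0 < core < 1.0:
            raise ValueError("probability unreachable for this observer")
        return self.threshold_db + self.slope_db * math.log(core / (1.0 - core))

    def __call__(self, snr_db: float, rng: np.random.Generator) -> bool:
        return bool(rng.uniform() < self.p_correct(snr_db))


def psychometric_response(observer: ObserverModel, snr_db: float,
                          rng: np.random.Generator) -> bool:
    """Single Bernoulli response of the observer at the given SNR."""
    return observer(snr_db, rng)


# ---------------------------------------------------------------------------
# trial-level generators
# ---------------------------------------------------------------------------

def _ar1(n: int, step_sd: float, reversion: float, rng: np.random.Generator) -> np.ndarray:
    """Bounded random-walk drift: x[t] = (1 - k) x[t-1] + step_sd * eps."""
    if n == 0:
        return np.zeros(0)
    eps = rng.standard_normal(n) * step_sd
    return lfilter([1.0], [1.0, -(1.0 - reversion)], eps)


def _pupil_noise(n: int, sd: float, tau_s: float, fs: float,
                 rng: np.random.Generator) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    phi = math.exp(-1.0 / (tau_s * fs))
    burn = int(5 * tau_s * fs)
    eps = rng.standard_normal(n + burn) * sd * math.sqrt(1.0 - phi * phi)
    return lfilter([1.0], [1.0, -phi], eps)[burn:]


def _raised_cosine_steps(n: int) -> np.ndarray:
    """Per-sample displacement fractions of a raised-cosine velocity profile."""
    k = np.arange(n)
    w = 1.0 - np.cos(2.0 * np.pi * (k + 0.5) / n)
    return w / w.sum()


def _sample_event_times(t0: float, t1: float, base_rate: float,
                        profile: RateProfile, refractory_s: float,
                        rng: np.random.Generator) -> list[float]:
    """Inhomogeneous Poisson thinning with an absolute refractory gap."""
    if base_rate <= 0:
        return []
    grid = np.linspace(t0, t1, 64)
    lam_max = base_rate * float(np.max(profile(grid)))
    if lam_max <= 0:
        return []
    times: list[float] = []
    t = t0
    while True:
        t += rng.exponential(1.0 / lam_max)
        if t >= t1:
            break
        if rng.uniform() >= base_rate * float(profile(np.array([t]))[0]) / lam_max:
            continue
        if times and t - times[-1] < refractory_s:
            continue
        times.append(t)
    return times


def _inject_saccades(x: np.ndarray, y: np.ndarray, fs: float, t_axis_start: float,
                     events: Sequence[tuple[float, float, float, float]],
                     shift_samples: int = 0) -> None:
    """Add ballistic displacements in place.

    ``events`` holds (onset_s, duration_ms, amplitude, angle); onsets are on
    the axis whose first sample is at ``t_axis_start``.
    """
    n = x.size
    dx_steps = np.zeros(n)
    dy_steps = np.zeros(n)
    for onset, duration_ms, amplitude, angle in events:
        i0 = int(round((onset - t_axis_start) * fs)) + shift_samples
        m = max(2, int(round(duration_ms / 1000.0 * fs)))
        if i0 < 0 or i0 + m > n:
            continue
        steps = _raised_cosine_steps(m) * amplitude
        dx_steps[i0:i0 + m] += steps * math.cos(angle)
        dy_steps[i0:i0 + m] += steps * math.sin(angle)
    x += np.cumsum(dx_steps)
    y += np.cumsum(dy_steps)


def phasic_template(t: np.ndarray, onset: float, peak_latency: float,
                    shape: float) -> np.ndarray:
    """Gamma-shaped unimodal bump, unit peak at ``peak_latency``.

    ``h(u) = u**a * exp(a * (1 - u))`` with ``u = (t - onset)/(tp - onset)``:
    a monotonic rise from sentence onset to a rounded peak, then a slow
    decay, matching the morphology of task-evoked pupil responses.
    """
    if peak_latency <= onset:
        raise ValueError("phasic peak latency must lie after the bump onset")
    u = np.clip((np.asarray(t, dtype=float) - onset) / (peak_latency - onset), 0.0, None)
    with np.errstate(over="ignore"):
        return u ** shape * np.exp(shape * (1.0 - u))


def simulate_trial_gaze(config: SimConfig, condition: str,
                        rng: np.random.Generator,
                        rate_scale: float = 1.0,
                        ) -> tuple[GazeRecording, list[InjectedMS], list[BlinkInterval]]:
    """One trial of binocular gaze on the trial-relative axis.

    Gaze = AR(1) drift + injected microsaccades (raised-cosine velocity,
    direction biased back toward fixation so gaze stays bounded, right-eye
    onset delayed by a uniform [0, 5] ms disparity).  Blinks are invalid
    spans in both eyes and the pupil channel.  The pupil channel is left at
    zero; :func:`simulate_trial_pupil` fills it per condition.
    """
    config.validate()
    lay = config.trial_layout
    fs = config.sampling_rate
    n = int(round(lay.duration * fs))
    t = lay.start + np.arange(n) / fs

    xl = _ar1(n, config.drift_sd, config.drift_reversion, rng)
    yl = _ar1(n, config.drift_sd, config.drift_reversion, rng)
    xr = _ar1(n, config.drift_sd, config.drift_reversion, rng)
    yr = _ar1(n, config.drift_sd, config.drift_reversion, rng)

    dur_lo, dur_hi = config.ms_duration_range_ms
    margin = 0.05 + dur_hi / 1000.0
    onsets = _sample_event_times(lay.start + margin, lay.end - margin,
                                 config.ms_base_rate * rate_scale,
                                 config.profile_for(condition),
                                 config.refractory_ms / 1000.0, rng)
    injected: list[InjectedMS] = []
    events_l: list[tuple[float, float, float, float]] = []
    events_r: list[tuple[float, float, float, float]] = []
    offset_x = offset_y = 0.0       # cumulative saccadic displacement so far
    for onset in onsets:
        duration_ms = rng.uniform(dur_lo, dur_hi)
        amplitude = rng.uniform(*config.ms_amplitude_range)
        # bias direction back toward fixation so gaze stays near the cross
        if math.hypot(offset_x, offset_y) > 1e-9:
            back = math.atan2(-offset_y, -offset_x)
            angle = back + rng.normal(0.0, 0.6)
        else:
            angle = rng.uniform(0.0, 2.0 * math.pi)
        disparity_s = rng.uniform(0.0, config.max_disparity_ms) / 1000.0
        events_l.append((onset, duration_ms, amplitude, angle))
        events_r.append((onset + disparity_s, duration_ms, amplitude, angle))
        offset_x += amplitude * math.cos(angle)
        offset_y += amplitude * math.sin(angle)
        injected.append(InjectedMS(participant="", trial=0, onset=onset,
                                   onset_rel=onset, duration_ms=duration_ms,
                                   amplitude=amplitude, angle=angle,
                                   condition=condition))
    _inject_saccades(xl, yl, fs, lay.start, events_l)
    _inject_saccades(xr, yr, fs, lay.start, events_r)

    valid_l = np.ones(n, dtype=bool)
    valid_r = np.ones(n, dtype=bool)
    blinks: list[BlinkInterval] = []
    if config.blink_rate_per_min > 0:
        n_blinks = rng.poisson(config.blink_rate_per_min * lay.duration / 60.0)
        for _ in range(n_blinks):
            dur = rng.uniform(*config.blink_duration_range_ms) / 1000.0
            start = rng.uniform(lay.start, lay.end - dur)
            i0 = int(round((start - lay.start) * fs))
            i1 = min(n, i0 + int(round(dur * fs)))
            valid_l[i0:i1] = False
            valid_r[i0:i1] = False
            blinks.append(BlinkInterval(participant="", trial=0,
                                        start=start, end=start + dur))
    if config.preonset_dropout_s > 0:
        i0 = int(round((-config.preonset_dropout_s - lay.start) * fs))
        i1 = int(round((0.0 - lay.start) * fs))
        valid_l[i0:i1] = False
        valid_r[i0:i1] = False

    pl = np.zeros(n)
    pr = np.zeros(n)
    for arr, valid in ((xl, valid_l), (yl, valid_l), (pl, valid_l),
                       (xr, valid_r), (yr, valid_r), (pr, valid_r)):
        arr[~valid] = np.nan
    rec = GazeRecording(sampling_rate=fs, time=t, xl=xl, yl=yl, pl=pl,
                        xr=xr, yr=yr, pr=pr, valid_l=valid_l, valid_r=valid_r,
                        events=[("trial_onset", 0.0)])
    return rec, injected, blinks


def simulate_trial_pupil(config: SimConfig, condition: str,
                         rng: np.random.Generator,
                         baseline: float = 0.0,
                         tonic: float | None = None,
                         amp: float | None = None,
                         peak_latency: float | None = None) -> np.ndarray:
    """One trial's pupil trace on the trial-relative axis (arbitrary units).

    trace = participant baseline + condition tonic offset + phasic bump +
    slow autocorrelated noise.  Blink masking is applied by the caller.
    """
    config.validate()
    lay = config.trial_layout
    fs = config.sampling_rate
    n = int(round(lay.duration * fs))
    t = lay.start + np.arange(n) / fs
    tonic = config.pupil_tonic[condition] if tonic is None else tonic
    amp = config.pupil_phasic_amp[condition] if amp is None else amp
    tp = config.pupil_phasic_peak_latency[condition] if peak_latency is None else peak_latency
    if not lay.sentence_onset < tp < lay.end:
        raise ValueError(f"phasic peak latency {tp} s outside the trial window")
    trace = baseline + tonic + amp * phasic_template(
        t, lay.sentence_onset, tp, config.pupil_phasic_shape)
    trace += _pupil_noise(n, config.noise_sd, config.noise_tau_s, fs, rng)
    return trace


def programmed_pd_curves(config: SimConfig) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Noiseless per-condition pupil templates on the trial-relative axis."""
    lay = config.trial_layout
    n = int(round(lay.duration * config.sampling_rate))
    t = lay.start + np.arange(n) / config.sampling_rate
    curves = {}
    for cond in config.conditions:
        curves[cond] = (config.pupil_tonic[cond]
                        + config.pupil_phasic_amp[cond]
                        * phasic_template(t, lay.sentence_onset,
                                          config.pupil_phasic_peak_latency[cond],
                                          config.pupil_phasic_shape))
    return t, curves


# ---------------------------------------------------------------------------
# experiment-level generator
# ---------------------------------------------------------------------------

def simulate_experiment(config: SimConfig) -> ExperimentData:
    """Full multi-participant dataset, reproducible from ``config.seed``.

    Per participant, trials are blocked by condition (in the order the
    condition dicts declare) and concatenated into one continuous recording
    with ``trial_onset`` events.  Between-participant variability is applied
    to pupil baseline, tonic offsets, phasic latency, and microsaccade base
    rate.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(max(config.n_participants, 1))
    lay = config.trial_layout
    fs = config.sampling_rate
    seg_n = int(round(lay.duration * fs))
    truth = GroundTruth()
    truth.time, truth.programmed_pd = programmed_pd_curves(config)
    participants: list[ParticipantRecording] = []

    for p in range(config.n_participants):
        rng = np.random.default_rng(children[p])
        pid = f"P{p:02d}"
        p_baseline = rng.normal(0.0, config.baseline_sd)
        p_tonic_shift = rng.normal(0.0, config.tonic_jitter_sd)
        p_rate_scale = max(0.1, rng.normal(1.0, config.rate_jitter_sd))
        p_latency_shift = rng.normal(0.0, config.latency_jitter_sd)

        chunks = []
        rows = []
        trial_idx = 0
        for cond in config.conditions:
            tp = config.pupil_phasic_peak_latency[cond] + p_latency_shift
            tp = float(np.clip(tp, lay.sentence_onset + 0.1, lay.end - 0.1))
            for _ in range(config.n_trials_per_condition):
                rec, injected, blinks = simulate_trial_gaze(
                    config, cond, rng, rate_scale=p_rate_scale)
                pupil = simulate_trial_pupil(
                    config, cond, rng, baseline=p_baseline,
                    tonic=config.pupil_tonic[cond] + p_tonic_shift,
                    peak_latency=tp)
                pupil = np.where(rec.valid_l, pupil, np.nan)
                rec.pl[:] = pupil
                rec.pr[:] = np.where(rec.valid_r, pupil, np.nan)
                t_offset = trial_idx * seg_n / fs
                onset_abs = t_offset + (0.0 - lay.start)
                for ev in injected:
                    ev.participant = pid
                    ev.trial = trial_idx
                    ev.onset = onset_abs + ev.onset_rel
                    truth.injected_ms.append(ev)
                for b in blinks:
                    truth.blink_intervals.append(BlinkInterval(
                        participant=pid, trial=trial_idx,
                        start=onset_abs + b.start, end=onset_abs + b.end))
                chunks.append(rec)
                rows.append({"trial": trial_idx, "condition": cond,
                             "onset_s": onset_abs})
                trial_idx += 1
        participants.append(ParticipantRecording(
            participant=pid,
            recording=_concatenate_trials(chunks, fs),
            trials=pd.DataFrame(rows, columns=["trial", "condition", "onset_s"]),
        ))
    return ExperimentData(participants=participants, ground_truth=truth,
                          config=config)


def _concatenate_trials(chunks: Sequence[GazeRecording], fs: float) -> GazeRecording:
    if not chunks:
        empty = np.zeros(0)
        return GazeRecording(sampling_rate=fs, time=empty, xl=empty, yl=empty,
                             pl=empty, xr=empty, yr=empty, pr=empty,
                             valid_l=np.zeros(0, bool), valid_r=np.zeros(0, bool))
    total = sum(c.n_samples for c in chunks)
    time = np.arange(total) / fs
    data = {c: np.empty(total) for c in ("xl", "yl", "pl", "xr", "yr", "pr")}
    valid_l = np.empty(total, dtype=bool)
    valid_r = np.empty(total, dtype=bool)
    events = []
    pos = 0
    for c in chunks:
        n = c.n_samples
        for name in data:
            data[name][pos:pos + n] = c.channel(name)
        valid_l[pos:pos + n] = c.valid_l
        valid_r[pos:pos + n] = c.valid_r
        for label, et in c.events:
            events.append((label, (et - c.time[0]) + pos / fs))
        pos += n
    return GazeRecording(sampling_rate=fs, time=time, **data,
                         valid_l=valid_l, valid_r=valid_r, events=events)


def simulate_fixation_recording(config: SimConfig,
                                n_trials: int = 100,
                                trial_duration_s: float = 5.0,
                                rng: np.random.Generator | None = None,
                                seed: int | None = None,
                                gap_samples: int = 10,
                                ) -> tuple[GazeRecording, list[InjectedMS]]:
    """Steady-fixation block: ``n_trials`` segments of drift + microsaccades
    at the configured base rate (flat profile, no blinks), separated by
    short masked gaps so detection runs cannot bridge segments.

    Returns the continuous recording plus the injected ground truth; the
    usable fixation time is ``n_trials * trial_duration_s``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.sampling_rate
    seg_n = int(round(trial_duration_s * fs))
    blocks = []
    truth: list[InjectedMS] = []
    pos = 0
    for k in range(n_trials):
        x_l = _ar1(seg_n, config.drift_sd, config.drift_reversion, rng)
        y_l = _ar1(seg_n, config.drift_sd, config.drift_reversion, rng)
        x_r = _ar1(seg_n, config.drift_sd, config.drift_reversion, rng)
        y_r = _ar1(seg_n, config.drift_sd, config.drift_reversion, rng)
        dur_lo, dur_hi = config.ms_duration_range_ms
        margin = 0.02 + dur_hi / 1000.0
        onsets = _sample_event_times(margin, trial_duration_s - margin,
                                     config.ms_base_rate, flat_profile,
                                     config.refractory_ms / 1000.0, rng)
        ev_l, ev_r = [], []
        off_x = off_y = 0.0
        for onset in onsets:
            duration_ms = rng.uniform(dur_lo, dur_hi)
            amplitude = rng.uniform(*config.ms_amplitude_range)
            if math.hypot(off_x, off_y) > 1e-9:
                angle = math.atan2(-off_y, -off_x) + rng.normal(0.0, 0.6)
            else:
                angle = rng.uniform(0.0, 2.0 * math.pi)
            disparity_s = rng.uniform(0.0, config.max_disparity_ms) / 1000.0
            ev_l.append((onset, duration_ms, amplitude, angle))
            ev_r.append((onset + disparity_s, duration_ms, amplitude, angle))
            off_x += amplitude * math.cos(angle)
            off_y += amplitude * math.sin(angle)
            truth.append(InjectedMS(participant="fix", trial=k,
                                    onset=pos / fs + onset, onset_rel=onset,
                                    duration_ms=duration_ms, amplitude=amplitude,
                                    angle=angle))
        _inject_saccades(x_l, y_l, fs, 0.0, ev_l)
        _inject_saccades(x_r, y_r, fs, 0.0, ev_r)
        blocks.append((x_l, y_l, x_r, y_r))
        pos += seg_n + gap_samples

    total = n_trials * seg_n + (n_trials - 1) * gap_samples if n_trials else 0
    time = np.arange(total) / fs
    arrays = {c: np.full(total, np.nan) for c in ("xl", "yl", "pl", "xr", "yr", "pr")}
    valid = np.zeros(total, dtype=bool)
    pos = 0
    for x_l, y_l, x_r, y_r in blocks:
        sl = slice(pos, pos + seg_n)
        arrays["xl"][sl], arrays["yl"][sl] = x_l, y_l
        arrays["xr"][sl], arrays["yr"][sl] = x_r, y_r
        arrays["pl"][sl] = 0.0
        arrays["pr"][sl] = 0.0
        valid[sl] = True
        pos += seg_n + gap_samples
    rec = GazeRecording(sampling_rate=fs, time=time, **arrays,
                        valid_l=valid.copy(), valid_r=valid.copy())
    return rec, truth
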