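"""Binocular microsaccade detection and smoothed rate estimation.

Detection follows the classical velocity-threshold approach for fixational
eye movements: gaze velocity is estimated with a 5-sample moving-window
stencil, thresholded at a multiple (lambda = 6 by default) of a
median-based standard deviation computed per subject and per axis, and
candidate events must

1. exceed the elliptical velocity threshold,
2. last between 5 and 100 ms,
3. occur in both eyes with onset disparity < 10 ms, and
4. be separated from the previous event by more than 50 ms.

Detected events are represented as unit pulses on the epoch axis, summed
across trials, normalized by trial count and sampling rate, and smoothed
with the causal kernel ``w(tau) = alpha**2 * tau * exp(-alpha * tau)``
(a standard spike-train rate kernel).  The kernel peaks at ``tau = 1/alpha``;
after convolution the time axis is shifted earlier by that peak so the
response to a pulse peaks at the pulse time.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .io_eyetrack import EpochSet, GazeRecording

#: default kernel characteristic time (s); the kernel peak sits here
DEFAULT_KERNEL_PEAK_S = 0.150
#: default decay parameter alpha (1/s), i.e. 1 / peak time
DEFAULT_ALPHA = 1.0 / DEFAULT_KERNEL_PEAK_S

_SIGMA_FLOOR = 1e-12


@dataclasses.dataclass
class DetectionParams:
    """Thresholds of the four admission criteria."""

    lambda_threshold: float = 6.0
    min_duration_ms: float = 5.0
    max_duration_ms: float = 100.0
    max_binocular_disparity_ms: float = 10.0
    min_inter_event_interval_ms: float = 50.0
    velocity_window: int = 5

    def __post_init__(self) -> None:
        if self.lambda_threshold <= 0:
            raise ValueError("lambda_threshold must be positive")
        if not 0 < self.min_duration_ms < self.max_duration_ms:
            raise ValueError("require 0 < min_duration < max_duration")
        if self.max_binocular_disparity_ms <= 0 or self.min_inter_event_interval_ms <= 0:
            raise ValueError("disparity and inter-event interval must be positive")
        if self.velocity_window != 5:
            raise ValueError("only the 5-sample velocity window is supported")


@dataclasses.dataclass
class MicrosaccadeEvent:
    onset: float               # s
    offset: float              # s
    duration_ms: float
    peak_velocity: float       # gaze-units / s
    amplitude: float           # gaze-units
    eye: str                   # "left", "right" or "binocular"


@dataclasses.dataclass
class VelocityEstimate:
    """Per-eye 2-D velocity series with a validity mask."""

    time: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    valid: np.ndarray
    sampling_rate: float


@dataclasses.dataclass
class RateSeries:
    """Smoothed events-per-second series on the epoch axis."""

    time: np.ndarray
    rate: np.ndarray           # events / s, >= 0
    alpha: float               # 1/s
    shift_applied: float       # s, equals the kernel peak
    n_trials: int


@dataclasses.dataclass
class Kernel:
    weights: np.ndarray
    dt: float
    alpha: float
    peak_index: int


# ---------------------------------------------------------------------------
# velocity and threshold scale
# ---------------------------------------------------------------------------

def _stencil_velocity(x: np.ndarray, dt: float) -> np.ndarray:
    v = np.full_like(x, np.nan)
    if x.size >= 5:
        v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt)
    return v


def compute_velocity(recording: GazeRecording, window: int = 5) -> dict[str, VelocityEstimate]:
    """Moving-window gaze velocity per eye.

    ``v[n] = (x[n+2] + x[n+1] - x[n-1] - x[n-2]) / (6 * dt)`` per axis; the
    estimator is exact on linear motion.  A velocity sample is masked when
    any raw sample in its 5-sample window is invalid, and at the two edge
    samples on each side.
    """
    if window != 5:
        raise ValueError("only the 5-sample window is supported")
    if recording.n_samples < window:
        raise ValueError("recording shorter than the velocity window")
    dt = 1.0 / recording.sampling_rate
    out: dict[str, VelocityEstimate] = {}
    for eye, xs, ys, valid in (("left", recording.xl, recording.yl, recording.valid_l),
                               ("right", recording.xr, recording.yr, recording.valid_r)):
        vx = _stencil_velocity(xs, dt)
        vy = _stencil_velocity(ys, dt)
        bad = np.convolve((~valid).astype(int), np.ones(window, dtype=int), mode="same") > 0
        ok = ~bad
        ok[:2] = False
        ok[-2:] = False
        ok &= np.isfinite(vx) & np.isfinite(vy)
        vx = np.where(ok, vx, np.nan)
        vy = np.where(ok, vy, np.nan)
        out[eye] = VelocityEstimate(time=recording.time, vx=vx, vy=vy, valid=ok,
                                    sampling_rate=recording.sampling_rate)
    return out


def median_sd(values: np.ndarray, valid: np.ndarray | None = None) -> float:
    """Median-based standard deviation ``sqrt(median(v^2) - median(v)^2)``.

    Computed over the valid samples of a subject's whole block; robust to
    the saccadic samples themselves.  A degenerate (near-zero) scale raises,
    because the velocity threshold would be meaningless.
    """
    v = np.asarray(values, dtype=float)
    if valid is not None:
        v = v[np.asarray(valid, dtype=bool)]
    v = v[np.isfinite(v)]
    if v.size < 5:
        raise ValueError("need at least 5 valid velocity samples")
    var = float(np.median(v ** 2) - np.median(v) ** 2)
    sigma = math.sqrt(max(var, 0.0))
    if sigma <= _SIGMA_FLOOR:
        raise ValueError("degenerate velocity scale (median-based SD ~ 0)")
    return sigma


def velocity_sigmas(velocities: dict[str, VelocityEstimate]) -> dict[str, tuple[float, float]]:
    """Per-eye (sigma_x, sigma_y) over a subject's block."""
    return {eye: (median_sd(v.vx, v.valid), median_sd(v.vy, v.valid))
            for eye, v in velocities.items()}


# ---------------------------------------------------------------------------
# detection chain
# ---------------------------------------------------------------------------

def detect_monocular(velocity: VelocityEstimate,
                     sigma: tuple[float, float],
                     params: DetectionParams,
                     x: np.ndarray | None = None,
                     y: np.ndarray | None = None,
                     eye: str = "left") -> list[MicrosaccadeEvent]:
    """Candidate events of one eye: elliptical threshold plus duration gate.

    A sample is above threshold iff
    ``(vx / (lambda * sigma_x))**2 + (vy / (lambda * sigma_y))**2 > 1``.
    Maximal above-threshold runs lasting 5-100 ms become candidates; runs
    adjacent to a velocity-masked sample (or the block edge) are discarded
    since their true extent is unknown.
    """
    sx, sy = sigma
    if sx <= _SIGMA_FLOOR or sy <= _SIGMA_FLOOR:
        raise ValueError("invalid sigma")
    lam = params.lambda_threshold
    with np.errstate(invalid="ignore"):
        ratio = (velocity.vx / (lam * sx)) ** 2 + (velocity.vy / (lam * sy)) ** 2
    above = velocity.valid & (ratio > 1.0)
    fs = velocity.sampling_rate
    n = above.size
    events: list[MicrosaccadeEvent] = []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = edges[above[edges + 1]] + 1
    stops = edges[~above[edges + 1]]          # inclusive end indices
    if above.size and above[0]:
        starts = np.concatenate(([0], starts))
    if above.size and above[-1]:
        stops = np.concatenate((stops, [n - 1]))
    for i0, i1 in zip(starts, stops):
        if i0 == 0 or i1 == n - 1:
            continue
        if not velocity.valid[i0 - 1] or not velocity.valid[i1 + 1]:
            continue
        duration_ms = (i1 - i0 + 1) / fs * 1000.0
        if not params.min_duration_ms <= duration_ms <= params.max_duration_ms:
            continue
        speed = np.hypot(velocity.vx[i0:i1 + 1], velocity.vy[i0:i1 + 1])
        if x is not None and y is not None:
            amplitude = float(np.hypot(x[i1] - x[i0], y[i1] - y[i0]))
        else:
            amplitude = float(np.sum(speed) / fs)   # path-length fallback
        events.append(MicrosaccadeEvent(
            onset=float(velocity.time[i0]),
            offset=float(velocity.time[i1]),
            duration_ms=float(duration_ms),
            peak_velocity=float(np.max(speed)),
            amplitude=amplitude,
            eye=eye,
        ))
    return events


def binocular_pair(left: Sequence[MicrosaccadeEvent],
                   right: Sequence[MicrosaccadeEvent],
                   params: DetectionParams) -> list[MicrosaccadeEvent]:
    """Greedy chronological pairing of monocular candidates.

    Each left candidate pairs with the earliest unpaired right candidate
    whose onset differs by strictly less than the disparity limit; unpaired
    candidates are dropped.  The binocular onset is the earlier monocular
    onset and the duration the longer monocular duration.
    """
    tol = params.max_binocular_disparity_ms / 1000.0
    left = sorted(left, key=lambda e: e.onset)
    right = sorted(right, key=lambda e: e.onset)
    used = [False] * len(right)
    out: list[MicrosaccadeEvent] = []
    j0 = 0
    for ev in left:
        while j0 < len(right) and (used[j0] or right[j0].onset <= ev.onset - tol):
            j0 += 1
        match = None
        for j in range(j0, len(right)):
            if right[j].onset >= ev.onset + tol:
                break
            if not used[j] and abs(right[j].onset - ev.onset) < tol:
                match = j
                break
        if match is None:
            continue
        used[match] = True
        other = right[match]
        onset = min(ev.onset, other.onset)
        duration_ms = max(ev.duration_ms, other.duration_ms)
        out.append(MicrosaccadeEvent(
            onset=onset,
            offset=onset + duration_ms / 1000.0,
            duration_ms=duration_ms,
            peak_velocity=max(ev.peak_velocity, other.peak_velocity),
            amplitude=0.5 * (ev.amplitude + other.amplitude),
            eye="binocular",
        ))
    out.sort(key=lambda e: e.onset)
    return out


def enforce_imi(events: Sequence[MicrosaccadeEvent],
                params: DetectionParams) -> list[MicrosaccadeEvent]:
    """Drop events whose onset is not more than the minimum interval after
    the previous *retained* event's onset (earlier event wins)."""
    gap = params.min_inter_event_interval_ms / 1000.0
    kept: list[MicrosaccadeEvent] = []
    for ev in sorted(events, key=lambda e: e.onset):
        if kept and ev.onset - kept[-1].onset <= gap:
            continue
        kept.append(ev)
    return kept


def detect_microsaccades(recording: GazeRecording,
                         params: DetectionParams | None = None,
                         sigma: dict[str, tuple[float, float]] | None = None,
                         ) -> list[MicrosaccadeEvent]:
    """Full detection chain: velocity -> sigma -> monocular -> pairing -> IMI.

    ``sigma`` may be supplied to reuse a scale estimated over a larger block
    of the same subject.  A recording with no gaze motion at all (all valid
    velocities zero) yields an empty list; a degenerate scale in the
    presence of motion is an error.
    """
    params = params or DetectionParams()
    vel = compute_velocity(recording, params.velocity_window)
    if sigma is None:
        try:
            sigma = velocity_sigmas(vel)
        except ValueError:
            peak = max(
                (float(np.nanmax(np.abs(np.where(v.valid, a, 0.0))))
                 for v in vel.values() for a in (v.vx, v.vy)
                 if v.valid.any()),
                default=0.0,
            )
            if peak <= _SIGMA_FLOOR:
                return []        # motionless block: nothing to detect
            raise
    left = detect_monocular(vel["left"], sigma["left"], params,
                            x=recording.xl, y=recording.yl, eye="left")
    right = detect_monocular(vel["right"], sigma["right"], params,
                             x=recording.xr, y=recording.yr, eye="right")
    events = enforce_imi(binocular_pair(left, right, params), params)
    _check_event_invariants(events, params)
    return events


def _check_event_invariants(events: Sequence[MicrosaccadeEvent],
                            params: DetectionParams) -> None:
    prev = None
    for ev in events:
        if not (params.min_duration_ms <= ev.duration_ms <= params.max_duration_ms):
            raise RuntimeError(f"event duration {ev.duration_ms} ms out of bounds")
        if ev.offset <= ev.onset or ev.peak_velocity <= 0:
            raise RuntimeError("malformed microsaccade event")
        if prev is not None and ev.onset - prev <= params.min_inter_event_interval_ms / 1000.0:
            raise RuntimeError("inter-event interval violated")
        prev = ev.onset


# ---------------------------------------------------------------------------
# rate estimation
# ---------------------------------------------------------------------------

def make_kernel(alpha: float = DEFAULT_ALPHA, dt: float = 1e-3,
                support: float | None = None) -> Kernel:
    """Discretize the causal rate kernel ``alpha**2 * tau * exp(-alpha*tau)``.

    The kernel is renormalized so that ``sum(w) * dt == 1``; its peak index
    is ``round((1/alpha)/dt)``.  The support must cover the tail: truncated
    tail mass above 1e-6 is an error (the default support of ``18/alpha``
    leaves ~3e-7).
    """
    if alpha <= 0 or dt <= 0:
        raise ValueError("alpha and dt must be positive")
    if support is None:
        support = 18.0 / alpha
    if support < 10.0 / alpha:
        raise ValueError("kernel support must be at least 10/alpha")
    tail = math.exp(-alpha * support) * (1.0 + alpha * support)
    if tail > 1e-6:
        raise ValueError(
            f"kernel support {support:g} s truncates {tail:.2e} of the mass (> 1e-6)")
    n = int(round(support / dt)) + 1
    tau = np.arange(n) * dt
    w = alpha ** 2 * tau * np.exp(-alpha * tau)
    w /= w.sum() * dt
    return Kernel(weights=w, dt=dt, alpha=alpha,
                  peak_index=int(round((1.0 / alpha) / dt)))


def rate_estimate(pulses: EpochSet, alpha: float = DEFAULT_ALPHA) -> RateSeries:
    """Trial-normalized smoothed event rate.

    ``raw(t) = sum_trials pulses(t) / n_trials * sampling_rate`` (events/s),
    causally convolved with the kernel and shifted earlier by the kernel
    peak so that the response to a pulse at ``t0`` peaks at ``t0``.
    """
    data = pulses.data
    if data.shape[0] < 1:
        raise ValueError("need at least one trial")
    if not np.all(np.isin(data, (0.0, 1.0))):
        raise ValueError("pulse epochs must contain only 0/1 values")
    fs = pulses.sampling_rate
    dt = 1.0 / fs
    n_trials = data.shape[0]
    raw = data.sum(axis=0) / n_trials * fs
    k = make_kernel(alpha, dt)
    conv = np.convolve(raw, k.weights)
    rate = conv[k.peak_index:k.peak_index + raw.size] * dt
    return RateSeries(time=pulses.time.copy(), rate=rate, alpha=alpha,
                      shift_applied=k.peak_index * dt, n_trials=n_trials)


def events_to_pulses(onsets_per_trial: Sequence[Sequence[float]],
                     time: np.ndarray,
                     conditions: Sequence | None = None,
                     participant: str = "") -> EpochSet:
    """Unit-pulse epochs from per-trial event onsets (s, on the epoch axis).

    Each onset is placed at its nearest sample; onsets outside the axis are
    ignored.
    """
    time = np.asarray(time, dtype=float)
    dt = float(time[1] - time[0])
    n_tr = len(onsets_per_trial)
    data = np.zeros((n_tr, time.size))
    for i, onsets in enumerate(onsets_per_trial):
        for t in onsets:
            idx = int(round((t - time[0]) / dt))
            if 0 <= idx < time.size:
                data[i, idx] = 1.0
    cond = conditions if conditions is not None else [""] * n_tr
    return EpochSet(data=data, time=time, condition=np.asarray(list(cond)),
                    missing=np.zeros_like(data, dtype=bool), participant=participant)


def patch_preonset_gap(pulses: EpochSet,
                       gap: tuple[float, float] = (-0.3, 0.0),
                       donor: tuple[float, float] = (-0.6, -0.3),
                       rng: np.random.Generator | None = None,
                       seed: int | None = None) -> EpochSet:
    """Repair a systematic pre-onset recording dropout.

    For every trial the gap window is overwritten with the donor window of a
    uniformly chosen *other* trial of the same participant.  Seeded and
    reproducible.
    """
    if pulses.n_trials < 2:
        raise ValueError("pre-onset patching needs at least 2 trials")
    if rng is None:
        rng = np.random.default_rng(seed)
    time = pulses.time
    fs = pulses.sampling_rate

    def window_slice(w):
        i0 = int(round((w[0] - time[0]) * fs))
        i1 = int(round((w[1] - time[0]) * fs))
        if i0 < 0 or i1 > time.size or i1 <= i0:
            raise ValueError(f"window {w} outside the epoch axis")
        return slice(i0, i1)

    g, d = window_slice(gap), window_slice(donor)
    if g.stop - g.start != d.stop - d.start:
        raise ValueError("gap and donor windows must have equal length")
    out = pulses.copy()
    n = pulses.n_trials
    for i in range(n):
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        out.data[i, g] = pulses.data[j, d]
        out.missing[i, g] = pulses.missing[j, d]
    return out


def events_table(events_by_trial: dict, path=None):
    """Flatten {(participant, condition, trial): [events]} into a table."""
    import pandas as pd

    rows = []
    for (participant, condition, trial), evs in events_by_trial.items():
        for ev in evs:
            rows.append({
                "participant": participant, "condition": condition, "trial": trial,
                "onset_s": ev.onset, "offset_s": ev.offset,
                "duration_ms": ev.duration_ms, "peak_velocity": ev.peak_velocity,
                "amplitude": ev.amplitude,
            })
    df = pd.DataFrame(rows, columns=["participant", "condition", "trial", "onset_s",
                                     "offset_s", "duration_ms", "peak_velocity",
                                     "amplitude"])
    if path is not None:
        df.to_csv(path, index=False)
    return df
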