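"""Pupillometry preprocessing chain and pupil-derived summary measures.

The chain (order fixed): mask fixation breaks -> epoch -> discard epochs
with >50% missing data -> linearly interpolate remaining gaps -> remove
trials where >=10% of samples deviate >3 SD from the per-time-point
condition mean -> z-score per participant across all retained trials of
both load conditions -> (optionally) baseline-correct against the
[-0.2, 0) s pre-onset window -> average per condition.

Only one eye (the left, by default) is analyzed.  Boundary conventions are
strict where the rules say "more than" (>50%, >3 SD, >100 px) and
inclusive where they say "or more" (>=10%).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_eyetrack import EpochSet, GazeRecording


@dataclasses.dataclass
class PupilParams:
    fixation_center: tuple[float, float] = (0.0, 0.0)
    fixation_radius: float = 100.0          # pixels / gaze-units, strict >
    participant_missing_max: float = 0.5    # strict >
    epoch_missing_max: float = 0.5          # strict >
    outlier_z: float = 3.0                  # strict >
    outlier_fraction: float = 0.10          # inclusive >=
    baseline_window: tuple[float, float] = (-0.2, 0.0)
    load_window: tuple[float, float] = (2.0, 5.0)
    eye: str = "left"

    def __post_init__(self) -> None:
        for name in ("participant_missing_max", "epoch_missing_max", "outlier_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.fixation_radius <= 0 or self.outlier_z <= 0:
            raise ValueError("radius and outlier threshold must be positive")
        if self.eye not in ("left", "right"):
            raise ValueError("eye must be 'left' or 'right'")


def _window_index(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    idx = (time >= window[0]) & (time < window[1])
    if not idx.any():
        raise ValueError(f"window {window} contains no samples of the epoch axis")
    return idx


def mask_fixation_breaks(recording: GazeRecording,
                         params: PupilParams | None = None) -> GazeRecording:
    """Mark samples with gaze strictly farther than the fixation radius from
    the cross (or already invalid, e.g. blinks) as missing, for the
    analyzed eye.  A sample at exactly the radius is retained."""
    params = params or PupilParams()
    rec = recording.copy()
    cx, cy = params.fixation_center
    if params.eye == "left":
        x, y = rec.xl, rec.yl
        valid = rec.valid_l
        channels = (rec.xl, rec.yl, rec.pl)
    else:
        x, y = rec.xr, rec.yr
        valid = rec.valid_r
        channels = (rec.xr, rec.yr, rec.pr)
    with np.errstate(invalid="ignore"):
        away = np.hypot(x - cx, y - cy) > params.fixation_radius
    new_valid = valid & ~away
    for ch in channels:
        ch[~new_valid] = np.nan
    if params.eye == "left":
        rec.valid_l = new_valid
    else:
        rec.valid_r = new_valid
    return rec


def participant_excluded(recording: GazeRecording,
                         params: PupilParams | None = None) -> tuple[bool, float]:
    """Whether the participant's overall missing fraction (analyzed eye,
    after masking) strictly exceeds the limit; returns the fraction too."""
    params = params or PupilParams()
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    valid = recording.valid_l if params.eye == "left" else recording.valid_r
    frac = 1.0 - float(valid.mean())
    return frac > params.participant_missing_max, frac


def clean_epochs(epochs: EpochSet,
                 params: PupilParams | None = None) -> tuple[EpochSet, dict]:
    """Missing-data epoch rejection, gap interpolation, outlier-trial removal.

    (a) epochs with a missing fraction strictly above the limit are dropped;
    (b) remaining gaps are filled by linear interpolation between nearest
        valid neighbors (edge gaps extend the nearest valid value);
    (c) per time point, the condition mean and SD are computed over the
        surviving trials; a trial is dropped when at least the outlier
        fraction of its samples deviates by more than ``outlier_z`` SDs
        from the per-time-point mean of its own condition.

    A condition left without trials is an error.  The report counts drops
    per rule.
    """
    params = params or PupilParams()
    conditions = epochs.conditions()
    n_input = epochs.n_trials

    frac_missing = epochs.missing.mean(axis=1)
    keep = frac_missing <= params.epoch_missing_max
    _require_all_conditions(epochs.condition[keep], conditions, "missing-data rule")
    kept = epochs.subset(np.flatnonzero(keep))
    n_dropped_missing = int(n_input - kept.n_trials)

    data = kept.data.copy()
    idx = np.arange(data.shape[1])
    for i in range(data.shape[0]):
        miss = kept.missing[i]
        if miss.any():
            data[i, miss] = np.interp(idx[miss], idx[~miss], data[i, ~miss])
    interpolated = EpochSet(data=data, time=kept.time, condition=kept.condition,
                            missing=np.zeros_like(data, dtype=bool),
                            participant=kept.participant)

    outlier = np.zeros(interpolated.n_trials, dtype=bool)
    for cond in conditions:
        rows = np.flatnonzero(interpolated.condition == cond)
        block = interpolated.data[rows]
        mean = block.mean(axis=0)
        sd = block.std(axis=0)
        with np.errstate(invalid="ignore"):
            deviant = np.abs(block - mean) > params.outlier_z * sd
        frac = deviant.mean(axis=1)
        outlier[rows] = frac >= params.outlier_fraction
    _require_all_conditions(interpolated.condition[~outlier], conditions,
                            "outlier rule")
    cleaned = interpolated.subset(np.flatnonzero(~outlier))
    report = {
        "n_input": int(n_input),
        "dropped_missing": n_dropped_missing,
        "dropped_outlier": int(outlier.sum()),
        "n_output": int(cleaned.n_trials),
    }
    return cleaned, report


def _require_all_conditions(labels: np.ndarray, conditions, rule: str) -> None:
    for cond in conditions:
        if not np.any(labels == cond):
            raise ValueError(f"condition {str(cond)!r} lost all trials at the {rule}")


def zscore_participant(epochs: EpochSet) -> tuple[EpochSet, dict]:
    """z-score with one mean/SD pooled over all retained samples of all
    conditions of the participant (not per time point)."""
    values = epochs.data
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("need at least two distinct pooled values to z-score")
    mean = float(values.mean())
    sd = float(values.std())
    if sd <= 1e-12:
        raise ValueError("zero pooled SD; cannot z-score")
    out = epochs.copy()
    out.data = (values - mean) / sd
    return out, {"mean": mean, "sd": sd}


def baseline_correct(epochs: EpochSet,
                     window: tuple[float, float] = (-0.2, 0.0)) -> EpochSet:
    """Subtract each trial's mean over the pre-onset window (half-open)."""
    idx = _window_index(epochs.time, window)
    out = epochs.copy()
    out.data = epochs.data - epochs.data[:, idx].mean(axis=1, keepdims=True)
    return out


def condition_mean(epochs: EpochSet) -> dict:
    """Per-condition trial-mean trace for one participant."""
    out = {}
    for cond in epochs.conditions():
        rows = epochs.condition == cond
        if not rows.any():
            raise ValueError(f"no trials in condition {cond!r}")
        out[cond] = epochs.data[rows].mean(axis=0)
    if not out:
        raise ValueError("epoch set is empty")
    return out


def group_condition_mean(per_participant: list[dict]) -> dict:
    """Unweighted mean of the participant-level condition traces."""
    if not per_participant:
        raise ValueError("no participants")
    conds = per_participant[0].keys()
    out = {}
    for cond in conds:
        stack = np.vstack([p[cond] for p in per_participant])
        out[cond] = stack.mean(axis=0)
    return out


def pd_peak(time: np.ndarray, trace: np.ndarray,
            search_window: tuple[float, float]) -> tuple[float, float]:
    """Latency and amplitude of the maximum within the window (half-open).

    Ties resolve to the earliest time.  An all-missing window is an error.
    """
    idx = _window_index(np.asarray(time), search_window)
    seg = np.asarray(trace, dtype=float)[idx]
    t_seg = np.asarray(time)[idx]
    finite = np.isfinite(seg)
    if not finite.any():
        raise ValueError("search window contains no finite samples")
    seg = np.where(finite, seg, -np.inf)
    i = int(np.argmax(seg))
    return float(t_seg[i]), float(seg[i])


def pd_load_effect(time: np.ndarray, hl_trace: np.ndarray, ll_trace: np.ndarray,
                   window: tuple[float, float] = (2.0, 5.0)) -> float:
    """Load effect: mean of (HL - LL) over the post-onset window."""
    hl = np.asarray(hl_trace, dtype=float)
    ll = np.asarray(ll_trace, dtype=float)
    if hl.shape != ll.shape:
        raise ValueError("traces must share the time axis")
    idx = _window_index(np.asarray(time), window)
    return float((hl[idx] - ll[idx]).mean())


def blink_rate(epochs: EpochSet | list[EpochSet]) -> tuple[np.ndarray, np.ndarray]:
    """Missing-data incidence at each time point (fraction of trials),
    pooled across the supplied epoch sets (participants)."""
    sets = epochs if isinstance(epochs, list) else [epochs]
    if not sets:
        raise ValueError("no epochs supplied")
    masks = np.vstack([e.missing for e in sets])
    return sets[0].time, masks.mean(axis=0)
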