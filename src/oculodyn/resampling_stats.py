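"""Participant-level bootstrap inference on condition-difference time series.

For each participant a condition-difference trace is computed; the
across-participant mean trace is then bootstrapped by resampling
participants with replacement (1000 iterations by default).  A time point
is deemed significant when the proportion of bootstrap iteration means
falling above (or below) zero exceeds the criterion (0.99), i.e. two
one-sided 1% tests per time point.  No correction across time points is
applied; contiguous significant runs are reported as intervals.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass
class DifferenceMatrix:
    """Per-participant condition-difference traces (participants x time)."""

    values: np.ndarray
    time: np.ndarray
    participants: list[str]
    condition_pair: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.time = np.asarray(self.time, dtype=float)
        if self.values.shape[1] != self.time.size:
            raise ValueError("row width differs from time axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("difference matrix contains non-finite values")

    @property
    def n_participants(self) -> int:
        return int(self.values.shape[0])


@dataclasses.dataclass
class SignificanceMask:
    time: np.ndarray
    prop_above: np.ndarray
    prop_below: np.ndarray
    significant: np.ndarray
    n_iterations: int
    criterion: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.prop_above + self.prop_below > 1.0 + 1e-12):
            raise ValueError("tail proportions exceed 1")


def condition_difference(traces: Mapping[str, Mapping[str, np.ndarray]],
                         pair: tuple[str, str],
                         time: np.ndarray) -> DifferenceMatrix:
    """Stack per-participant ``trace[pair[0]] - trace[pair[1]]`` rows.

    ``traces`` maps participant -> condition -> trace on the shared axis.
    A participant missing either condition is an error.
    """
    a, b = pair
    rows = []
    participants = []
    for pid, conds in traces.items():
        if a not in conds or b not in conds:
            raise ValueError(f"participant {pid!r} lacks condition {a!r} or {b!r}")
        rows.append(np.asarray(conds[a], dtype=float) - np.asarray(conds[b], dtype=float))
        participants.append(pid)
    if not rows:
        raise ValueError("no participants supplied")
    return DifferenceMatrix(values=np.vstack(rows), time=np.asarray(time, dtype=float),
                            participants=participants, condition_pair=pair)


def bootstrap_mask(diff: DifferenceMatrix,
                   n_iterations: int = 1000,
                   criterion: float = 0.99,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None) -> SignificanceMask:
    """Pointwise bootstrap of the across-participant mean difference.

    Each iteration resamples participants with replacement and stores the
    mean trace.  ``prop_above(t)`` is the fraction of iteration means > 0
    (ties at zero count in neither tail); a point is significant when
    either tail proportion strictly exceeds the criterion.
    """
    n = diff.n_participants
    if n < 2:
        raise ValueError("bootstrap needs at least 2 participants")
    if not 0.5 < criterion < 1.0:
        raise ValueError("criterion must lie in (0.5, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_iterations, n))
    counts = np.zeros((n_iterations, n))
    for i in range(n_iterations):
        counts[i] = np.bincount(idx[i], minlength=n)
    means = (counts / n) @ diff.values          # (iterations, time)
    prop_above = (means > 0).mean(axis=0)
    prop_below = (means < 0).mean(axis=0)
    significant = (prop_above > criterion) | (prop_below > criterion)
    return SignificanceMask(time=diff.time.copy(), prop_above=prop_above,
                            prop_below=prop_below, significant=significant,
                            n_iterations=n_iterations, criterion=criterion, seed=seed)


def significant_intervals(mask: SignificanceMask,
                          min_length: int = 1) -> list[tuple[float, float, int]]:
    """Maximal runs of significant samples of one sign.

    Returns ``(start_s, end_s, sign)`` per run, where start/end are the
    times of the first and last significant sample and sign is +1 when the
    effect exceeds zero.  Runs shorter than ``min_length`` samples are
    dropped; a sign change splits a run.
    """
    sig = np.asarray(mask.significant, dtype=bool)
    sign = np.where(mask.prop_above > mask.criterion, 1, -1)
    out: list[tuple[float, float, int]] = []
    i = 0
    n = sig.size
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        if j - i + 1 >= min_length:
            out.append((float(mask.time[i]), float(mask.time[j]), int(sign[i])))
        i = j + 1
    return out


def write_mask_csv(mask: SignificanceMask, path) -> None:
    pd.DataFrame({
        "time_s": mask.time,
        "prop_above": mask.prop_above,
        "prop_below": mask.prop_below,
        "significant": mask.significant.astype(int),
    }).to_csv(path, index=False)


def read_difference_csv(path) -> DifferenceMatrix:
    """Long CSV (participant, time_s, value) -> DifferenceMatrix."""
    df = pd.read_csv(path)
    pids = list(dict.fromkeys(df["participant"]))
    time = df[df["participant"] == pids[0]]["time_s"].to_numpy(dtype=float)
    rows = [df[df["participant"] == p]["value"].to_numpy(dtype=float) for p in pids]
    return DifferenceMatrix(values=np.vstack(rows), time=time,
                            participants=[str(p) for p in pids])
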