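"""Binocular eye-tracker sample I/O and peristimulus epoching.

Two on-disk representations are supported:

* an EyeLink-ASC-style *text dialect*: one sample per line
  (``<time_ms> <xl> <yl> <pl> <xr> <yr> <pr>``, tab separated, ``.`` for a
  missing field) with ``MSG <time_ms> <label>`` event lines; and
* a canonical delimited table (CSV with explicit validity columns).

Epoching cuts a continuous recording into fixed peristimulus windows
(``[-2, 5.5)`` s by default) around event onsets.  Windows are half-open in
samples so an epoch has a fixed length at any sampling rate.  Onsets that
fall between samples are aligned to the nearest sample.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: channel names of the canonical sample table, in column order
SAMPLE_CHANNELS = ("xl", "yl", "pl", "xr", "yr", "pr")

_LEFT_CHANNELS = frozenset({"xl", "yl", "pl"})
_RIGHT_CHANNELS = frozenset({"xr", "yr", "pr"})

#: default peristimulus analysis window in seconds (half-open)
DEFAULT_WINDOW = (-2.0, 5.5)

_TIME_TOL = 1e-9


@dataclasses.dataclass
class GazeRecording:
    """Continuous binocular samples on a uniform time axis.

    Masked (invalid) samples carry ``NaN`` in the data channels and a
    ``False`` bit in the per-eye validity mask; consumers must ignore the
    values at masked samples.
    """

    sampling_rate: float
    time: np.ndarray
    xl: np.ndarray
    yl: np.ndarray
    pl: np.ndarray
    xr: np.ndarray
    yr: np.ndarray
    pr: np.ndarray
    valid_l: np.ndarray
    valid_r: np.ndarray
    events: list[tuple[str, float]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.time = np.asarray(self.time, dtype=float)
        for name in SAMPLE_CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.time.shape:
                raise ValueError(f"channel {name!r} length differs from time axis")
        self.valid_l = np.asarray(self.valid_l, dtype=bool)
        self.valid_r = np.asarray(self.valid_r, dtype=bool)
        if self.valid_l.shape != self.time.shape or self.valid_r.shape != self.time.shape:
            raise ValueError("validity masks must match the time axis")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValueError(f"time axis not strictly increasing at sample {i + 1}")
            if np.any(np.abs(dt - 1.0 / self.sampling_rate) > _TIME_TOL):
                raise ValueError("time axis is not uniform at the declared sampling rate")

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        if name not in SAMPLE_CHANNELS:
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)

    def validity_for(self, channel: str) -> np.ndarray:
        """Validity mask of the eye a channel belongs to."""
        if channel in _LEFT_CHANNELS:
            return self.valid_l
        if channel in _RIGHT_CHANNELS:
            return self.valid_r
        raise KeyError(f"unknown channel {channel!r}")

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            sampling_rate=self.sampling_rate,
            time=self.time.copy(),
            xl=self.xl.copy(), yl=self.yl.copy(), pl=self.pl.copy(),
            xr=self.xr.copy(), yr=self.yr.copy(), pr=self.pr.copy(),
            valid_l=self.valid_l.copy(), valid_r=self.valid_r.copy(),
            events=list(self.events),
        )


@dataclasses.dataclass
class EpochSet:
    """Trials x time matrix of one channel on a shared peristimulus axis."""

    data: np.ndarray           # (n_trials, n_time)
    time: np.ndarray           # seconds relative to onset
    condition: np.ndarray      # (n_trials,) labels
    missing: np.ndarray        # (n_trials, n_time) bool
    participant: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.time = np.asarray(self.time, dtype=float)
        self.condition = np.asarray(self.condition)
        self.missing = np.atleast_2d(np.asarray(self.missing, dtype=bool))
        if self.data.shape != self.missing.shape:
            raise ValueError("data and missing mask shapes differ")
        if self.data.shape[1] != self.time.size:
            raise ValueError("data width differs from time axis")
        if self.condition.size != self.data.shape[0]:
            raise ValueError("one condition label per trial required")

    @property
    def n_trials(self) -> int:
        return int(self.data.shape[0])

    @property
    def sampling_rate(self) -> float:
        if self.time.size < 2:
            raise ValueError("cannot infer sampling rate from <2 samples")
        return 1.0 / float(self.time[1] - self.time[0])

    def conditions(self) -> list:
        seen: list = []
        for c in self.condition:
            if c not in seen:
                seen.append(c)
        return seen

    def select(self, condition) -> "EpochSet":
        keep = self.condition == condition
        return self.subset(np.flatnonzero(keep))

    def subset(self, index) -> "EpochSet":
        index = np.asarray(index)
        return EpochSet(
            data=self.data[index],
            time=self.time,
            condition=self.condition[index],
            missing=self.missing[index],
            participant=self.participant,
        )

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.time.copy(), self.condition.copy(),
                        self.missing.copy(), self.participant)


# ---------------------------------------------------------------------------
# ASC-style text dialect
# ---------------------------------------------------------------------------

def _fmt(value: float, valid: bool) -> str:
    if not valid or not np.isfinite(value):
        return "."
    return repr(float(value))


def write_asc(recording: GazeRecording, path) -> None:
    """Write a recording in the ASC-style dialect (timestamps in ms).

    One line per sample; masked samples serialize their eye's fields as
    ``.``.  Events are written as ``MSG`` lines interleaved in time order.
    """
    path = Path(path)
    events = sorted(recording.events, key=lambda e: e[1])
    ei = 0
    lines = ["** oculodyn ASC dialect",
             f"** RATE {recording.sampling_rate:g}"]
    for i in range(recording.n_samples):
        t = recording.time[i]
        while ei < len(events) and events[ei][1] <= t + _TIME_TOL:
            label, et = events[ei]
            lines.append(f"MSG\t{_ms(et)}\t{label}")
            ei += 1
        vl, vr = bool(recording.valid_l[i]), bool(recording.valid_r[i])
        fields = [_ms(t)]
        fields += [_fmt(recording.channel(c)[i], vl) for c in ("xl", "yl", "pl")]
        fields += [_fmt(recording.channel(c)[i], vr) for c in ("xr", "yr", "pr")]
        lines.append("\t".join(fields))
    for label, et in events[ei:]:
        lines.append(f"MSG\t{_ms(et)}\t{label}")
    path.write_text("\n".join(lines) + "\n")


def _ms(t_s: float) -> str:
    ms = t_s * 1000.0
    r = round(ms)
    if abs(ms - r) < 1e-6:
        return str(int(r))
    return repr(ms)


def read_asc(path, sampling_rate: float = 1000.0) -> GazeRecording:
    """Parse the ASC-style dialect into a :class:`GazeRecording`.

    ``.`` or absent fields mask the corresponding eye's sample.  Unknown
    line types are skipped (a count is logged).  Nonmonotonic sample
    timestamps are a hard error naming the first offending line.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    path = Path(path)
    times: list[float] = []
    cols: dict[str, list[float]] = {c: [] for c in SAMPLE_CHANNELS}
    valid_l: list[bool] = []
    valid_r: list[bool] = []
    events: list[tuple[str, float]] = []
    skipped = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("**"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            head = parts[0]
            if head == "MSG":
                if len(parts) >= 3:
                    events.append(("\t".join(parts[2:]), float(parts[1]) / 1000.0))
                else:
                    skipped += 1
                continue
            try:
                t = float(head) / 1000.0
            except ValueError:
                skipped += 1
                continue
            if times and t <= times[-1]:
                raise ValueError(
                    f"nonmonotonic sample timestamp at line {lineno} of {path.name}")
            times.append(t)
            values = parts[1:7] + ["."] * max(0, 6 - len(parts[1:7]))
            parsed = [np.nan if v == "." else float(v) for v in values]
            vl = all(np.isfinite(parsed[:3]))
            vr = all(np.isfinite(parsed[3:]))
            if not vl:
                parsed[:3] = [np.nan] * 3
            if not vr:
                parsed[3:] = [np.nan] * 3
            for c, v in zip(SAMPLE_CHANNELS, parsed):
                cols[c].append(v)
            valid_l.append(vl)
            valid_r.append(vr)
    if skipped:
        logger.info("read_asc: skipped %d unknown line(s) in %s", skipped, path.name)
    return GazeRecording(
        sampling_rate=sampling_rate,
        time=np.asarray(times),
        **{c: np.asarray(v) for c, v in cols.items()},
        valid_l=np.asarray(valid_l, dtype=bool),
        valid_r=np.asarray(valid_r, dtype=bool),
        events=events,
    )


# ---------------------------------------------------------------------------
# canonical delimited tables
# ---------------------------------------------------------------------------

def write_samples_csv(recording: GazeRecording, path) -> None:
    df = pd.DataFrame({"time_s": recording.time})
    for c in SAMPLE_CHANNELS:
        df[c] = recording.channel(c)
    df["valid_l"] = recording.valid_l.astype(int)
    df["valid_r"] = recording.valid_r.astype(int)
    df.to_csv(path, index=False)


def read_samples_csv(path, sampling_rate: float | None = None,
                     events: list[tuple[str, float]] | None = None) -> GazeRecording:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time_s"].to_numpy(dtype=float)
    if sampling_rate is None:
        if t.size < 2:
            raise ValueError("cannot infer sampling rate from <2 samples")
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    return GazeRecording(
        sampling_rate=sampling_rate,
        time=t,
        **{c: df[c].to_numpy(dtype=float) for c in SAMPLE_CHANNELS},
        valid_l=df["valid_l"].to_numpy().astype(bool),
        valid_r=df["valid_r"].to_numpy().astype(bool),
        events=list(events or []),
    )


def write_events_csv(events: Sequence[tuple], path,
                     columns=("trial", "condition", "onset_s")) -> None:
    pd.DataFrame(list(events), columns=list(columns)).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epoch_by_events(recording: GazeRecording,
                    onsets: Sequence[float],
                    window: tuple[float, float] = DEFAULT_WINDOW,
                    channel: str = "pl",
                    conditions: Sequence | None = None,
                    participant: str = "") -> EpochSet:
    """Cut fixed peristimulus epochs around each onset.

    The sample window is half-open, ``[onset + window[0], onset + window[1])``,
    so at 1000 Hz the default window yields exactly 7500 samples per epoch.
    Each onset is aligned to the nearest sample of the recording.
    """
    if window[1] <= window[0]:
        raise ValueError("window end must exceed window start")
    fs = recording.sampling_rate
    n_time = int(round((window[1] - window[0]) * fs))
    rel = window[0] + np.arange(n_time) / fs
    values = recording.channel(channel)
    valid = recording.validity_for(channel)
    n = recording.n_samples
    t0 = recording.time[0] if n else 0.0

    data = np.empty((len(onsets), n_time))
    missing = np.empty((len(onsets), n_time), dtype=bool)
    for k, onset in enumerate(onsets):
        i0 = int(round((onset - t0) * fs))
        start = i0 + int(round(window[0] * fs))
        stop = start + n_time
        if start < 0 or stop > n:
            raise ValueError(
                f"trial {k}: epoch window [{onset + window[0]:g}, "
                f"{onset + window[1]:g}) s falls outside the recording")
        data[k] = values[start:stop]
        missing[k] = ~valid[start:stop]
    if conditions is None:
        conditions = [""] * len(onsets)
    return EpochSet(data=data, time=rel, condition=np.asarray(list(conditions)),
                    missing=missing, participant=participant)


def write_epochs_csv(epochs: EpochSet, path) -> None:
    """Serialize epochs in long format (trial, condition, time_s, value, missing)."""
    n_tr, n_t = epochs.data.shape
    df = pd.DataFrame({
        "trial": np.repeat(np.arange(n_tr), n_t),
        "condition": np.repeat(epochs.condition, n_t),
        "time_s": np.tile(epochs.time, n_tr),
        "value": epochs.data.ravel(),
        "missing": epochs.missing.ravel().astype(int),
    })
    df.to_csv(path, index=False)


def read_epochs_csv(path, participant: str = "") -> EpochSet:
    df = pd.read_csv(path, float_precision="round_trip")
    trials = np.unique(df["trial"].to_numpy())
    first = df[df["trial"] == trials[0]]
    time = first["time_s"].to_numpy(dtype=float)
    data = np.empty((trials.size, time.size))
    missing = np.empty_like(data, dtype=bool)
    cond = []
    for i, tr in enumerate(trials):
        sub = df[df["trial"] == tr]
        data[i] = sub["value"].to_numpy(dtype=float)
        missing[i] = sub["missing"].to_numpy().astype(bool)
        cond.append(sub["condition"].iloc[0])
    return EpochSet(data=data, time=time, condition=np.asarray(cond),
                    missing=missing, participant=participant)
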