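"""One-up-one-down adaptive SNR staircase (speech-reception threshold).

The procedure tracks the 50%-correct point of a listener: a correct
response lowers the SNR by the current step, an incorrect one raises it.
A *reversal* is logged at a trial whose induced direction differs from the
previously established direction; the step size drops to the next schedule
entry immediately after each reversal (12 -> 8 -> 5 -> 2 dB floor).  The
run ends after a fixed number of reversals or a trial cap, whichever comes
first, and the threshold is the mean SNR of the final reversals.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

ObserverFn = Callable[[float, np.random.Generator], bool]


@dataclasses.dataclass
class StaircaseConfig:
    initial_snr: float = 20.0
    step_schedule: tuple[float, ...] = (12.0, 8.0, 5.0)
    step_floor: float = 2.0
    max_reversals: int = 7
    max_trials: int = 25
    reversals_for_threshold: int = 4
    clamp: tuple[float, float] | None = None   # optional SNR limits, off by default

    def __post_init__(self) -> None:
        steps = list(self.step_schedule)
        if any(s <= 0 for s in steps) or self.step_floor <= 0:
            raise ValueError("all step sizes must be positive")
        if any(b >= a for a, b in zip(steps, steps[1:])):
            raise ValueError("step schedule must be strictly decreasing")
        if steps and self.step_floor > steps[-1]:
            raise ValueError("step floor must not exceed the last scheduled step")
        if self.max_trials < self.max_reversals:
            raise ValueError("max_trials must be at least max_reversals")
        if self.reversals_for_threshold <= 0:
            raise ValueError("reversals_for_threshold must be positive")

    def step_after(self, n_reversals: int) -> float:
        """Step size in force once ``n_reversals`` reversals have occurred."""
        if n_reversals < len(self.step_schedule):
            return self.step_schedule[n_reversals]
        return self.step_floor


@dataclasses.dataclass
class StaircaseResult:
    trial_snrs: list[float]
    responses: list[bool]
    steps: list[float]                 # step applied after each trial
    reversal_trials: list[int]
    reversal_snrs: list[float]
    threshold: float | None
    termination: str                   # "reversals" or "trial_cap"


def run_staircase(observer: ObserverFn,
                  config: StaircaseConfig | None = None,
                  rng: np.random.Generator | None = None) -> StaircaseResult:
    """Run one adaptive track against a response source.

    ``observer(snr_db, rng) -> bool`` supplies the per-trial correctness
    (a :class:`~oculodyn.synth.ObserverModel` instance is callable this way).
    The first trial has no previous direction, so the first reversal
    requires one established direction.
    """
    config = config or StaircaseConfig()
    rng = rng or np.random.default_rng()
    snr = float(config.initial_snr)
    direction = 0                      # -1 down, +1 up, 0 not yet established
    n_reversals = 0
    trial_snrs: list[float] = []
    responses: list[bool] = []
    steps: list[float] = []
    reversal_trials: list[int] = []
    reversal_snrs: list[float] = []
    termination = "trial_cap"

    for trial in range(config.max_trials):
        try:
            correct = bool(observer(snr, rng))
        except Exception as exc:       # annotate with trial context
            raise RuntimeError(f"observer failed at trial {trial}") from exc
        trial_snrs.append(snr)
        responses.append(correct)
        new_direction = -1 if correct else +1
        if direction != 0 and new_direction != direction:
            reversal_trials.append(trial)
            reversal_snrs.append(snr)
            n_reversals += 1
        direction = new_direction
        step = config.step_after(n_reversals)
        steps.append(step)
        if n_reversals >= config.max_reversals:
            termination = "reversals"
            break
        snr = snr + new_direction * step
        if config.clamp is not None:
            snr = float(np.clip(snr, *config.clamp))

    threshold = threshold_from_reversals(
        reversal_snrs, k=config.reversals_for_threshold)
    return StaircaseResult(trial_snrs=trial_snrs, responses=responses, steps=steps,
                           reversal_trials=reversal_trials, reversal_snrs=reversal_snrs,
                           threshold=threshold, termination=termination)


def threshold_from_reversals(reversal_snrs: Sequence[float] | StaircaseResult,
                             k: int = 4) -> float | None:
    """Mean SNR of the final ``k`` reversals; ``None`` when fewer occurred."""
    if isinstance(reversal_snrs, StaircaseResult):
        reversal_snrs = reversal_snrs.reversal_snrs
    if k <= 0:
        raise ValueError("k must be positive")
    if len(reversal_snrs) < k:
        return None
    return float(np.mean(list(reversal_snrs)[-k:]))


def low_load_snr(threshold_db: float, offset_db: float = 10.0) -> float:
    """Low-load condition SNR: the estimated threshold plus a fixed relief
    (10 dB), making the task much easier at an otherwise matched level."""
    return threshold_db + offset_db
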