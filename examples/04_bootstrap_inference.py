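"""Participant-level bootstrap significance masks.

Builds per-participant condition-difference traces with an effect confined
to 1.0-2.0 s, bootstraps the across-participant mean (1000 iterations,
two one-sided 1% criteria), and reports the significant intervals.
"""

import numpy as np

from oculodyn import bootstrap_mask, condition_difference, significant_intervals

rng = np.random.default_rng(3)
time = -2.0 + np.arange(750) / 100.0
traces = {}
for p in range(31):
    effect = np.where((time >= 1.0) & (time < 2.0), 0.5, 0.0)
    traces[f"P{p:02d}"] = {
        "HL": effect + rng.normal(0, 1.0, time.size) * 0.5,
        "LL": rng.normal(0, 1.0, time.size) * 0.5,
    }

diff = condition_difference(traces, ("HL", "LL"), time)
mask = bootstrap_mask(diff, n_iterations=1000, criterion=0.99, seed=7)
intervals = significant_intervals(mask, min_length=5)

print(f"significant fraction of time points: {mask.significant.mean():.3f}")
for start, end, sign in intervals:
    print(f"  interval {start:+.2f} .. {end:+.2f} s  sign {sign:+d}")
print("The mask should flag (only) the programmed 1-2 s effect window;")
print("isolated flickers elsewhere reflect the uncorrected pointwise test.")
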