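"""Causal-kernel event-rate estimation on unit pulse trains.

Places a single event pulse at 1.0 s and shows that, after the peak-shift
correction, the smoothed response peaks exactly at the pulse time with
height alpha/e; then recovers a homogeneous 1.2 events/s rate from many
Poisson pulse trains.
"""

import numpy as np

from oculodyn import DEFAULT_ALPHA, events_to_pulses, make_kernel, rate_estimate

time = -2.0 + np.arange(7500) / 1000.0

k = make_kernel(DEFAULT_ALPHA, 1e-3)
print(f"kernel mass (should be 1): {k.weights.sum() * k.dt:.9f}")
print(f"kernel peak at tau = {k.peak_index} ms, height {k.weights[k.peak_index]:.4f} /s")

series = rate_estimate(events_to_pulses([[1.0]], time), DEFAULT_ALPHA)
i = int(np.argmax(series.rate))
print(f"single pulse at 1.0 s -> rate peak {series.rate[i]:.4f} /s at {series.time[i]:.3f} s")

rng = np.random.default_rng(0)
onsets = [list(rng.uniform(-2, 5.5, rng.poisson(1.2 * 7.5))) for _ in range(300)]
series = rate_estimate(events_to_pulses(onsets, time), DEFAULT_ALPHA)
sel = (series.time > -1.0) & (series.time < 4.5)
print(f"300 Poisson trains at 1.2 events/s -> mean rate {series.rate[sel].mean():.3f} /s")
print("The peak height alpha/e (~2.45 /s for a 150 ms kernel) is the kernel's")
print("closed-form maximum; the recovered mean approaches the true rate.")
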