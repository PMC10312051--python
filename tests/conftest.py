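import numpy as np
import pytest

from oculodyn.io_eyetrack import GazeRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(n=100, fs=1000.0, seed=0, missing=(), events=()):
    """Small random recording; ``missing`` holds (eye, index) pairs."""
    r = np.random.default_rng(seed)
    time = np.arange(n) / fs
    chans = {c: r.normal(size=n) for c in ("xl", "yl", "pl", "xr", "yr", "pr")}
    valid_l = np.ones(n, dtype=bool)
    valid_r = np.ones(n, dtype=bool)
    for eye, i in missing:
        if eye == "left":
            valid_l[i] = False
            for c in ("xl", "yl", "pl"):
                chans[c][i] = np.nan
        else:
            valid_r[i] = False
            for c in ("xr", "yr", "pr"):
                chans[c][i] = np.nan
    return GazeRecording(sampling_rate=fs, time=time, **chans,
                         valid_l=valid_l, valid_r=valid_r, events=list(events))


@pytest.fixture
def make_rec():
    return make_recording
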