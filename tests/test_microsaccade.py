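"""Detection-chain criteria, kernel closed forms, and rate estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculodyn.io_eyetrack import EpochSet, GazeRecording
from oculodyn.microsaccade import (DEFAULT_ALPHA, DetectionParams,
                                   MicrosaccadeEvent, VelocityEstimate,
                                   binocular_pair, compute_velocity,
                                   detect_microsaccades, enforce_imi,
                                   events_to_pulses, make_kernel, median_sd,
                                   patch_preonset_gap, rate_estimate,
                                   detect_monocular, velocity_sigmas)
from oculodyn.synth import SimConfig, simulate_fixation_recording
from .conftest import make_recording


def quiet_recording(n=2000, drift=0.002, seed=0):
    cfg = SimConfig(ms_base_rate=0.0, blink_rate_per_min=0.0, drift_sd=drift)
    rec, _ = simulate_fixation_recording(cfg, n_trials=1,
                                         trial_duration_s=n / 1000.0, seed=seed)
    return rec


# ---------------------------------------------------------------- velocity

def test_velocity_exact_on_linear_motion():
    """The 5-sample stencil is exact on x(t) = c*t."""
    rec = make_recording(n=100)
    c = 3.7
    for ch in ("xl", "yl", "xr", "yr"):
        rec.channel(ch)[:] = c * rec.time
    vel = compute_velocity(rec)
    for eye in ("left", "right"):
        v = vel[eye]
        np.testing.assert_allclose(v.vx[v.valid], c, atol=1e-9)
        np.testing.assert_allclose(v.vy[v.valid], c, atol=1e-9)


def test_velocity_zero_on_constant_position():
    rec = make_recording(n=50)
    for ch in ("xl", "yl", "xr", "yr"):
        rec.channel(ch)[:] = 1.23
    vel = compute_velocity(rec)
    np.testing.assert_allclose(vel["left"].vx[vel["left"].valid], 0.0, atol=1e-12)


def test_velocity_matches_independent_stencil_oracle():
    """Loop-coded centered stencil agrees with the vectorized estimator."""
    rec = make_recording(n=300, seed=5)
    vel = compute_velocity(rec)["left"]
    dt = 1e-3
    x = rec.xl
    for n in range(2, 298):
        expect = (x[n + 2] + x[n + 1] - x[n - 1] - x[n - 2]) / (6 * dt)
        assert vel.vx[n] == pytest.approx(expect, abs=1e-9)


def test_velocity_masked_around_invalid_samples():
    rec = make_recording(n=100, missing=[("left", 50)])
    vel = compute_velocity(rec)
    left = vel["left"]
    assert not left.valid[48:53].any()     # 5-sample window overlaps the gap
    assert left.valid[45] and left.valid[55]
    assert vel["right"].valid[50]          # other eye unaffected


def test_velocity_window_too_long_errors():
    rec = make_recording(n=3)
    with pytest.raises(ValueError):
        compute_velocity(rec)


# ---------------------------------------------------------------- median SD

def test_median_sd_hand_computed_value():
    """v = {-2,-1,0,1,2}: median(v^2)=1, median(v)=0, sigma=1."""
    assert median_sd(np.array([-2.0, -1.0, 0.0, 1.0, 2.0])) == 1.0


def test_median_sd_degenerate_errors():
    with pytest.raises(ValueError, match="degenerate"):
        median_sd(np.full(10, 3.3))
    with pytest.raises(ValueError, match="5 valid"):
        median_sd(np.array([1.0, 2.0]))


@settings(max_examples=30, derandomize=True, deadline=None)
@given(k=st.floats(min_value=-100, max_value=100).filter(lambda k: abs(k) > 1e-3),
       seed=st.integers(0, 1000))
def test_median_sd_scale_equivariance(k, seed):
    v = np.random.default_rng(seed).normal(size=50)
    assert median_sd(k * v) == pytest.approx(abs(k) * median_sd(v), rel=1e-9)


# ---------------------------------------------------------------- detection

def _vel(vx, vy, fs=1000.0):
    n = len(vx)
    valid = np.ones(n, dtype=bool)
    valid[:2] = valid[-2:] = False
    return VelocityEstimate(time=np.arange(n) / fs, vx=np.asarray(vx, float),
                            vy=np.asarray(vy, float), valid=valid,
                            sampling_rate=fs)


def test_monocular_short_burst_rejected():
    """A 3-ms above-threshold burst fails the 5-100 ms duration gate."""
    vx = np.zeros(100)
    vx[50:53] = 100.0
    events = detect_monocular(_vel(vx, np.zeros(100)), (1.0, 1.0),
                              DetectionParams())
    assert events == []


def test_monocular_long_run_rejected():
    vx = np.zeros(300)
    vx[50:200] = 100.0                      # 150 ms > 100 ms cap
    assert detect_monocular(_vel(vx, np.zeros(300)), (1.0, 1.0),
                            DetectionParams()) == []


def test_monocular_accepts_valid_run_with_elliptical_threshold():
    vx = np.zeros(100)
    vy = np.zeros(100)
    vx[40:60] = 5.0                         # (5/6)^2 + (5/6)^2 > 1 jointly
    vy[40:60] = 5.0
    events = detect_monocular(_vel(vx, vy), (1.0, 1.0), DetectionParams())
    assert len(events) == 1
    ev = events[0]
    assert ev.onset == pytest.approx(0.040) and ev.duration_ms == 20.0
    # each axis alone sits below threshold: elliptical sum is what passes
    assert detect_monocular(_vel(vx, np.zeros(100)), (1.0, 1.0),
                            DetectionParams()) == []


def test_zero_velocity_no_candidates():
    assert detect_monocular(_vel(np.zeros(50), np.zeros(50)), (1.0, 1.0),
                            DetectionParams()) == []


def _ev(onset, dur=0.02):
    return MicrosaccadeEvent(onset=onset, offset=onset + dur, duration_ms=dur * 1e3,
                             peak_velocity=50.0, amplitude=0.5, eye="left")


def test_binocular_pairing_within_disparity():
    out = binocular_pair([_ev(1.0)], [_ev(1.005)], DetectionParams())
    assert len(out) == 1 and out[0].onset == 1.0 and out[0].eye == "binocular"


def test_monocular_only_event_dropped():
    assert binocular_pair([_ev(1.0)], [], DetectionParams()) == []
    assert binocular_pair([], [_ev(1.0)], DetectionParams()) == []


def test_disparity_boundary_is_strict():
    """Exactly 10 ms onset disparity does not pair."""
    assert binocular_pair([_ev(1.0)], [_ev(1.010)], DetectionParams()) == []
    assert len(binocular_pair([_ev(1.0)], [_ev(1.0099)], DetectionParams())) == 1


def test_pairing_is_greedy_chronological():
    left = [_ev(1.0), _ev(1.2)]
    right = [_ev(1.004), _ev(1.196)]
    out = binocular_pair(left, right, DetectionParams())
    assert [e.onset for e in out] == [1.0, 1.196]


def test_imi_rule():
    p = DetectionParams()
    out = enforce_imi([_ev(1.0), _ev(1.03)], p)      # 30 ms apart
    assert [e.onset for e in out] == [1.0]
    out = enforce_imi([_ev(1.0), _ev(1.06)], p)      # 60 ms apart
    assert [e.onset for e in out] == [1.0, 1.06]
    assert enforce_imi([], p) == []


def test_detection_scale_invariance():
    """Scaling all gaze coordinates by k leaves detected onsets unchanged."""
    cfg = SimConfig(seed=21, blink_rate_per_min=0.0)
    rec, _ = simulate_fixation_recording(cfg, n_trials=5, seed=21)
    base = detect_microsaccades(rec)
    assert len(base) >= 3
    scaled = rec.copy()
    for ch in ("xl", "yl", "xr", "yr"):
        scaled.channel(ch)[:] *= 37.0
    again = detect_microsaccades(scaled)
    np.testing.assert_allclose([e.onset for e in again], [e.onset for e in base])


def test_detected_events_satisfy_invariants():
    cfg = SimConfig(seed=5, blink_rate_per_min=0.0)
    rec, _ = simulate_fixation_recording(cfg, n_trials=10, seed=5)
    events = detect_microsaccades(rec)
    onsets = np.array([e.onset for e in events])
    assert (np.diff(onsets) > 0.05).all()
    for e in events:
        assert 5.0 <= e.duration_ms <= 100.0
        assert e.peak_velocity > 0


def test_detector_recall_on_injected_events():
    """High-amplitude injections are recovered at their onset times."""
    cfg = SimConfig(seed=2, blink_rate_per_min=0.0,
                    ms_amplitude_range=(0.8, 1.2),
                    ms_duration_range_ms=(10.0, 25.0))
    rec, truth = simulate_fixation_recording(cfg, n_trials=10, seed=2)
    det = np.array([e.onset for e in detect_microsaccades(rec)])
    inj = np.array([e.onset for e in truth])
    assert len(inj) >= 40
    hits = sum(np.any(np.abs(det - t) < 0.010) for t in inj)
    assert hits / len(inj) >= 0.95


def test_all_masked_recording_yields_no_events():
    rec = make_recording(n=500)
    rec.valid_l[:] = False
    rec.valid_r[:] = False
    for c in ("xl", "yl", "pl", "xr", "yr", "pr"):
        rec.channel(c)[:] = np.nan
    assert detect_microsaccades(rec) == []


def test_motionless_recording_yields_no_events():
    rec = make_recording(n=500)
    for c in ("xl", "yl", "xr", "yr"):
        rec.channel(c)[:] = 2.0
    assert detect_microsaccades(rec) == []


# ---------------------------------------------------------------- kernel/rate

def test_kernel_mass_normalized():
    k = make_kernel(DEFAULT_ALPHA, 1e-3)
    assert k.weights.sum() * k.dt == pytest.approx(1.0, abs=1e-9)


def test_kernel_peak_location_and_height():
    """Continuous peak at tau = 1/alpha with height alpha/e (~2.4525 /s for
    a 150 ms characteristic time)."""
    k = make_kernel(DEFAULT_ALPHA, 1e-3)
    assert k.peak_index == 150
    assert int(np.argmax(k.weights)) == k.peak_index
    assert k.weights[k.peak_index] == pytest.approx(DEFAULT_ALPHA * math.exp(-1),
                                                    rel=1e-3)


def test_kernel_support_too_short_errors():
    with pytest.raises(ValueError):
        make_kernel(DEFAULT_ALPHA, 1e-3, support=0.5)      # below 10/alpha
    with pytest.raises(ValueError, match="mass"):
        make_kernel(DEFAULT_ALPHA, 1e-3, support=1.6)      # tail still > 1e-6


def test_single_pulse_rate_peaks_at_pulse_time():
    time = -2.0 + np.arange(7500) / 1000.0
    pulses = events_to_pulses([[1.0]], time)
    series = rate_estimate(pulses, DEFAULT_ALPHA)
    assert series.shift_applied == pytest.approx(0.150)
    i = int(np.argmax(series.rate))
    assert series.time[i] == pytest.approx(1.0, abs=1e-3)
    assert series.rate[i] == pytest.approx(DEFAULT_ALPHA * math.exp(-1), rel=1e-3)


def test_zero_pulses_zero_rate():
    time = np.arange(1000) / 1000.0
    series = rate_estimate(events_to_pulses([[], []], time))
    np.testing.assert_array_equal(series.rate, 0.0)


def test_rate_conservation_before_smoothing():
    """sum_t raw(t) * dt * n_trials equals the retained event count."""
    time = np.arange(5000) / 1000.0
    onsets = [[0.5, 1.2], [2.0], [], [3.3, 4.1, 4.9]]
    pulses = events_to_pulses(onsets, time)
    n_events = sum(len(o) for o in onsets)
    raw = pulses.data.sum(axis=0) / len(onsets) * 1000.0
    assert raw.sum() * 1e-3 * len(onsets) == pytest.approx(n_events)


def test_smoothing_preserves_total_mass():
    """integral(rate) == integral(raw) for pulses away from the epoch end."""
    time = np.arange(8000) / 1000.0
    pulses = events_to_pulses([[1.0, 2.5], [3.0]], time)
    series = rate_estimate(pulses)
    raw_mass = pulses.data.sum() / pulses.n_trials
    assert series.rate.sum() * 1e-3 == pytest.approx(raw_mass, rel=1e-6)


def test_poisson_pulses_recover_rate():
    """Homogeneous pulse trains at rate r average to r events/s."""
    r, n_trials, T = 1.2, 200, 6.0
    rng = np.random.default_rng(0)
    time = np.arange(int(T * 1000)) / 1000.0
    onsets = [list(rng.uniform(0, T, rng.poisson(r * T))) for _ in range(n_trials)]
    series = rate_estimate(events_to_pulses(onsets, time))
    # interior window avoids the causal edge losses
    sel = (series.time > 1.0) & (series.time < 5.0)
    se = math.sqrt(r / (n_trials * T))
    assert abs(series.rate[sel].mean() - r) < 3 * se


def test_rate_rejects_non_binary_pulses():
    time = np.arange(100) / 1000.0
    ep = EpochSet(data=np.full((1, 100), 0.5), time=time,
                  condition=np.array(["A"]), missing=np.zeros((1, 100), bool))
    with pytest.raises(ValueError):
        rate_estimate(ep)


# ---------------------------------------------------------------- patching

def _pulse_set(data):
    data = np.asarray(data, dtype=float)
    time = -1.0 + np.arange(data.shape[1]) / 1000.0
    return EpochSet(data=data, time=time,
                    condition=np.array(["A"] * data.shape[0]),
                    missing=np.zeros_like(data, dtype=bool))


def test_patch_identical_trials_is_identity():
    """With identical trials (and donor content equal to gap content) the
    patch is the identity; pulses outside both windows are never touched."""
    data = np.zeros((4, 2000))
    data[:, 1500] = 1.0                     # t = 0.5 s, outside both windows
    pulses = _pulse_set(data)
    out = patch_preonset_gap(pulses, gap=(-0.3, 0.0), donor=(-0.6, -0.3), seed=0)
    np.testing.assert_array_equal(out.data, pulses.data)


def test_patch_single_trial_errors():
    with pytest.raises(ValueError, match="2 trials"):
        patch_preonset_gap(_pulse_set(np.zeros((1, 2000))), seed=0)


def test_patch_deterministic_and_donor_sourced():
    rng = np.random.default_rng(3)
    data = (rng.uniform(size=(6, 2000)) < 0.01).astype(float)
    pulses = _pulse_set(data)
    a = patch_preonset_gap(pulses, seed=42)
    b = patch_preonset_gap(pulses, seed=42)
    np.testing.assert_array_equal(a.data, b.data)
    # axis starts at -1.0 s at 1000 Hz: gap = samples [700, 1000),
    # donor = samples [400, 700)
    gap, donor = slice(700, 1000), slice(400, 700)
    outside = np.ones(2000, dtype=bool)
    outside[gap] = False
    np.testing.assert_array_equal(a.data[:, outside], pulses.data[:, outside])
    # each patched gap equals some other trial's donor window
    for i in range(6):
        matches = [j for j in range(6) if j != i
                   and np.array_equal(a.data[i, gap], pulses.data[j, donor])]
        assert matches


def test_patch_window_outside_axis_errors():
    with pytest.raises(ValueError, match="outside"):
        patch_preonset_gap(_pulse_set(np.zeros((3, 500))),
                           gap=(-0.3, 0.0), donor=(-2.0, -1.7), seed=0)
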