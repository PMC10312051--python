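"""Pupil preprocessing rules, boundary conventions, and summary measures."""

import numpy as np
import pytest

from oculodyn.io_eyetrack import EpochSet
from oculodyn.pupil import (PupilParams, baseline_correct, blink_rate,
                            clean_epochs, condition_mean, group_condition_mean,
                            mask_fixation_breaks, participant_excluded,
                            pd_load_effect, pd_peak, zscore_participant)
from .conftest import make_recording


def epochs_from(data, conditions=None, missing=None, t0=-2.0, fs=1000.0):
    data = np.asarray(data, dtype=float)
    time = t0 + np.arange(data.shape[1]) / fs
    if conditions is None:
        conditions = ["A"] * data.shape[0]
    if missing is None:
        missing = np.zeros_like(data, dtype=bool)
    return EpochSet(data=data, time=time, condition=np.asarray(conditions),
                    missing=np.asarray(missing, dtype=bool))


# ------------------------------------------------------------ gaze masking

def test_fixation_break_boundaries():
    """>100 px from the cross is missing; exactly 100 px is retained."""
    rec = make_recording(n=4)
    rec.xl[:] = [0.0, 101.0, 100.0, 99.0]
    rec.yl[:] = 0.0
    out = mask_fixation_breaks(rec, PupilParams())
    np.testing.assert_array_equal(out.valid_l, [True, False, True, True])
    assert np.isnan(out.pl[1]) and np.isfinite(out.pl[2])
    # already-invalid samples (blinks) stay missing
    rec2 = make_recording(n=3, missing=[("left", 1)])
    rec2.xl[[0, 2]] = 0.0
    rec2.yl[[0, 2]] = 0.0
    out2 = mask_fixation_breaks(rec2, PupilParams())
    np.testing.assert_array_equal(out2.valid_l, [True, False, True])


def test_participant_exclusion_boundaries():
    """Strictly more than 50% missing excludes; exactly 50% retains."""
    rec = make_recording(n=10, missing=[("left", i) for i in range(6)])
    excluded, frac = participant_excluded(rec, PupilParams())
    assert excluded and frac == pytest.approx(0.6)
    rec = make_recording(n=10, missing=[("left", i) for i in range(5)])
    excluded, frac = participant_excluded(rec, PupilParams())
    assert not excluded and frac == pytest.approx(0.5)
    excluded, _ = participant_excluded(make_recording(n=10), PupilParams())
    assert not excluded
    with pytest.raises(ValueError):
        participant_excluded(make_recording(n=0), PupilParams())


# ------------------------------------------------------------ epoch cleaning

def test_epochs_over_half_missing_dropped():
    data = np.ones((3, 100))
    missing = np.zeros((3, 100), dtype=bool)
    missing[1, :51] = True                  # 51% missing -> dropped
    missing[2, :50] = True                  # exactly 50% -> retained
    cleaned, report = clean_epochs(epochs_from(data, missing=missing))
    assert cleaned.n_trials == 2
    assert report["dropped_missing"] == 1 and report["dropped_outlier"] == 0


def test_fully_valid_constant_epochs_untouched():
    data = np.full((5, 50), 2.5)
    cleaned, report = clean_epochs(epochs_from(data))
    np.testing.assert_array_equal(cleaned.data, data)
    assert report == {"n_input": 5, "dropped_missing": 0,
                      "dropped_outlier": 0, "n_output": 5}


def test_gap_interpolation_linear_and_edge_hold():
    data = np.arange(10, dtype=float)[None, :].repeat(2, axis=0)
    missing = np.zeros((2, 10), dtype=bool)
    missing[0, 4] = True                    # interior gap
    missing[0, 0] = True                    # edge gap -> nearest-valid hold
    data[0, [0, 4]] = np.nan
    cleaned, _ = clean_epochs(epochs_from(data, missing=missing))
    assert cleaned.data[0, 4] == pytest.approx(4.0)     # between 3 and 5
    assert cleaned.data[0, 0] == pytest.approx(1.0)     # held from sample 1
    assert not cleaned.missing.any()


def test_outlier_trial_dropped_by_direct_rule_evaluation():
    """20 identical epochs plus one displaced by +10 SD-equivalents over 15%
    of samples: exactly the displaced epoch falls to the 3-SD/10% rule."""
    rng = np.random.default_rng(0)
    base = rng.normal(0.0, 1.0, size=100)
    data = np.vstack([base] * 21)
    data[20, :15] += 10.0
    cleaned, report = clean_epochs(epochs_from(data))
    assert report["dropped_outlier"] == 1 and cleaned.n_trials == 20
    np.testing.assert_array_equal(cleaned.data, data[:20])
    # independent check of the rule on the displaced row
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    frac = (np.abs(data[20] - mean) > 3 * sd).mean()
    assert frac >= 0.10


def test_condition_emptied_raises():
    data = np.ones((2, 40))
    missing = np.zeros_like(data, dtype=bool)
    missing[0, :] = True
    with pytest.raises(ValueError, match="condition 'A'"):
        clean_epochs(epochs_from(data, conditions=["A", "B"], missing=missing))


# ------------------------------------------------------------ z-scoring

def test_zscore_pooled_moments():
    rng = np.random.default_rng(1)
    data = rng.normal(3.0, 2.0, size=(6, 200))
    z, stats = zscore_participant(epochs_from(data, conditions=["A"] * 3 + ["B"] * 3))
    assert z.data.mean() == pytest.approx(0.0, abs=1e-9)
    assert z.data.std() == pytest.approx(1.0, abs=1e-9)
    assert stats["mean"] == pytest.approx(data.mean())


def test_zscore_constant_input_errors():
    with pytest.raises(ValueError):
        zscore_participant(epochs_from(np.full((2, 10), 7.0)))


def test_zscore_two_condition_offsets_against_brute_force():
    """Known offsets 2 and 4: transformed means differ by 2/pooled SD."""
    rng = np.random.default_rng(2)
    noise = rng.normal(0.0, 1.0, size=(8, 100))
    data = noise + np.array([2.0] * 4 + [4.0] * 4)[:, None]
    ep = epochs_from(data, conditions=["A"] * 4 + ["B"] * 4)
    z, _ = zscore_participant(ep)
    pooled_sd = data.std()                              # brute-force oracle
    got = z.data[4:].mean() - z.data[:4].mean()
    want = (data[4:].mean() - data[:4].mean()) / pooled_sd
    assert got == pytest.approx(want, abs=1e-12)


# ------------------------------------------------------------ baseline

def test_baseline_mean_zero_after_correction():
    rng = np.random.default_rng(3)
    ep = epochs_from(rng.normal(size=(4, 3000)))
    out = baseline_correct(ep, (-0.2, 0.0))
    idx = (out.time >= -0.2) & (out.time < 0.0)
    np.testing.assert_allclose(out.data[:, idx].mean(axis=1), 0.0, atol=1e-12)


def test_baseline_constant_epoch_to_zero():
    out = baseline_correct(epochs_from(np.full((2, 3000), 5.0)), (-0.2, 0.0))
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


def test_baseline_ramp_subtracts_window_mean():
    """x(t) = t: the subtracted value is the exact mean of the window samples."""
    time = -2.0 + np.arange(3000) / 1000.0
    ep = epochs_from(time[None, :])
    out = baseline_correct(ep, (-0.2, 0.0))
    idx = (time >= -0.2) & (time < 0.0)
    expected = time - time[idx].mean()
    np.testing.assert_allclose(out.data[0], expected, atol=1e-12)


def test_baseline_window_outside_axis_errors():
    with pytest.raises(ValueError):
        baseline_correct(epochs_from(np.ones((1, 100)), t0=0.0), (-0.2, 0.0))


# ------------------------------------------------------------ averaging

def test_condition_mean_identical_trials():
    data = np.vstack([np.arange(10.0)] * 3)
    traces = condition_mean(epochs_from(data))
    np.testing.assert_array_equal(traces["A"], np.arange(10.0))


def test_condition_mean_of_two_trials():
    data = np.vstack([np.zeros(10), np.full(10, 2.0)])
    traces = condition_mean(epochs_from(data))
    np.testing.assert_array_equal(traces["A"], 1.0)


def test_condition_and_group_mean_match_direct_summation():
    rng = np.random.default_rng(4)
    per_part = []
    acc = []
    for _ in range(3):
        data = rng.normal(size=(5, 30))
        per_part.append(condition_mean(epochs_from(data)))
        acc.append(data.mean(axis=0))
    group = group_condition_mean(per_part)
    np.testing.assert_allclose(group["A"], np.mean(acc, axis=0), atol=1e-12)


# ------------------------------------------------------------ summaries

def test_pd_peak_of_programmed_bump():
    from oculodyn.synth import phasic_template
    time = -2.0 + np.arange(7500) / 1000.0
    trace = phasic_template(time, 0.5, 3.0, 8.0)
    lat, amp = pd_peak(time, trace, (0.5, 5.5))
    assert lat == pytest.approx(3.0, abs=1e-3)
    assert amp == pytest.approx(1.0, rel=1e-6)


def test_pd_peak_monotone_and_tie_rules():
    time = np.arange(100) / 100.0
    lat, _ = pd_peak(time, time.copy(), (0.2, 0.8))
    assert lat == pytest.approx(time[(time >= 0.2) & (time < 0.8)][-1])
    lat, _ = pd_peak(time, np.ones(100), (0.2, 0.8))   # ties -> earliest
    assert lat == pytest.approx(0.2)
    with pytest.raises(ValueError):
        pd_peak(time, np.full(100, np.nan), (0.2, 0.8))


def test_pd_load_effect_cases():
    time = np.arange(7500) / 1000.0 - 2.0
    hl = np.zeros_like(time)
    ll = np.zeros_like(time)
    assert pd_load_effect(time, hl, ll) == 0.0
    assert pd_load_effect(time, hl + 0.4, ll) == pytest.approx(0.4)
    hl2 = np.where((time >= 2.0) & (time < 4.0), 0.3, 0.0)
    # effect present for 2 of the 3 s of the [2, 5) window -> 0.3 * 2/3
    assert pd_load_effect(time, hl2, ll) == pytest.approx(0.2, abs=1e-4)


def test_blink_incidence_fractions():
    data = np.zeros((10, 50))
    missing = np.zeros((10, 50), dtype=bool)
    missing[:2, 25] = True
    t, inc = blink_rate(epochs_from(data, missing=missing))
    assert inc[25] == pytest.approx(0.2)
    assert inc.sum() == pytest.approx(0.2)
    _, inc0 = blink_rate(epochs_from(np.zeros((4, 20))))
    np.testing.assert_array_equal(inc0, 0.0)


# ------------------------------------------------------------ chain oracle

def test_chain_matches_straight_line_oracle():
    """mask -> drop sparse -> interpolate -> drop outliers -> z-score ->
    baseline -> average, against an independently coded straight-line
    implementation on a small fixture."""
    rng = np.random.default_rng(5)
    n_tr, n_t = 8, 2400
    time = -2.0 + np.arange(n_t) / 1000.0
    data = rng.normal(0.0, 1.0, size=(n_tr, n_t))
    data[0] += np.where(time > 0, 0.5, 0.0)
    missing = rng.uniform(size=(n_tr, n_t)) < 0.02
    missing[1, :1300] = True                 # >50% missing
    data[missing] = np.nan
    conds = ["HL"] * 4 + ["LL"] * 4
    ep = epochs_from(data, conditions=conds, missing=missing)

    cleaned, _ = clean_epochs(ep)
    z, _ = zscore_participant(cleaned)
    bc = baseline_correct(z, (-0.2, 0.0))
    got = condition_mean(bc)

    # --- independent oracle, plain loops -------------------------------
    keep = [i for i in range(n_tr) if missing[i].mean() <= 0.5]
    interp = {}
    for i in keep:
        row = data[i].copy()
        good = np.flatnonzero(~missing[i])
        row = np.interp(np.arange(n_t), good, row[good])
        interp[i] = row
    surv = list(interp)
    for cond in ("HL", "LL"):
        rows = [i for i in surv if conds[i] == cond]
        block = np.vstack([interp[i] for i in rows])
        m, s = block.mean(0), block.std(0)
        for i in rows:
            if ((np.abs(interp[i] - m) > 3 * s).mean()) >= 0.10:
                surv.remove(i)
    pooled = np.concatenate([interp[i] for i in surv])
    mu, sd = pooled.mean(), pooled.std()
    base_idx = (time >= -0.2) & (time < 0.0)
    out = {}
    for cond in ("HL", "LL"):
        rows = []
        for i in surv:
            if conds[i] != cond:
                continue
            zi = (interp[i] - mu) / sd
            rows.append(zi - zi[base_idx].mean())
        out[cond] = np.mean(np.vstack(rows), axis=0)

    np.testing.assert_allclose(got["HL"], out["HL"], atol=1e-10)
    np.testing.assert_allclose(got["LL"], out["LL"], atol=1e-10)
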