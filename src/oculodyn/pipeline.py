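"""End-to-end seeded pipeline: simulate -> preprocess -> detect -> rate ->
bootstrap, reproducing figure-level outputs on synthetic data.

Every stage communicates through serialized-friendly containers, and the
run directory holds CSV traces/rates/masks, an events table, a JSON
summary, and a manifest with the config hash and per-stage counts, so any
stage can be re-run from its inputs.  Given the same config and seed the
outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_eyetrack import DEFAULT_WINDOW, epoch_by_events
from .microsaccade import (DEFAULT_ALPHA, DetectionParams, detect_microsaccades,
                           events_table, events_to_pulses, patch_preonset_gap,
                           rate_estimate)
from .pupil import (PupilParams, baseline_correct, blink_rate, clean_epochs,
                    condition_mean, group_condition_mean, mask_fixation_breaks,
                    participant_excluded, pd_load_effect, pd_peak,
                    zscore_participant)
from .resampling_stats import (bootstrap_mask, condition_difference,
                               significant_intervals, write_mask_csv)
from .synth import SimConfig, TrialLayout, dip_profile, simulate_experiment


@dataclasses.dataclass
class BootstrapSettings:
    n_iterations: int = 1000
    criterion: float = 0.99


@dataclasses.dataclass
class RunConfig:
    """Validated per-module parameter blocks plus one global seed.

    The global seed overrides ``sim.seed`` and deterministically derives
    the bootstrap seeds.
    """

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    pupil: PupilParams = dataclasses.field(default_factory=PupilParams)
    detection: DetectionParams = dataclasses.field(default_factory=DetectionParams)
    bootstrap: BootstrapSettings = dataclasses.field(default_factory=BootstrapSettings)
    alpha: float = DEFAULT_ALPHA
    baseline: bool = True
    patch_preonset: bool = False
    make_figures: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.sim.seed = self.seed
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_block = dict(raw.get("sim", {}))
        if "trial_layout" in sim_block:
            sim_block["trial_layout"] = TrialLayout(**sim_block["trial_layout"])
        if "ms_rate_dip" in sim_block:
            # convenience: {condition: [start, end, depth]} builds callables
            dips = sim_block.pop("ms_rate_dip")
            sim_block["ms_rate_profile"] = {
                c: dip_profile(*v) for c, v in dips.items()}
        return cls(
            sim=SimConfig(**sim_block),
            pupil=PupilParams(**raw.get("pupil", {})),
            detection=DetectionParams(**raw.get("detection", {})),
            bootstrap=BootstrapSettings(**raw.get("bootstrap", {})),
            alpha=raw.get("alpha", DEFAULT_ALPHA),
            baseline=raw.get("baseline", True),
            patch_preonset=raw.get("patch_preonset", False),
            make_figures=raw.get("make_figures", False),
            seed=raw.get("seed", 0),
        )


def demo_config(seed: int = 0, n_participants: int = 31,
                n_trials: int = 30) -> RunConfig:
    """Default demonstration: a high-load microsaccade-rate dip of 50% over
    [1.5, 2.8] s (smooth 0.3 s edges) plus the default tonic/phasic pupil
    load effects."""
    sim = SimConfig(
        n_participants=n_participants,
        n_trials_per_condition=n_trials,
        ms_rate_profile={"HL": dip_profile(1.5, 2.8, 0.5, ramp_s=0.3)},
        seed=seed,
    )
    return RunConfig(sim=sim, seed=seed)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage and write the run directory; returns the results.

    Raises with the stage name and participant context on failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    window = DEFAULT_WINDOW
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    boot_seed_pd = int(seeds[1].generate_state(1)[0] % (2 ** 31))
    boot_seed_ms = int(seeds[2].generate_state(1)[0] % (2 ** 31))

    exp = _stage("simulate", lambda: simulate_experiment(config.sim))
    conditions = config.sim.conditions
    pair = tuple(conditions[:2]) if len(conditions) >= 2 else None

    pd_traces_z: dict[str, dict[str, np.ndarray]] = {}
    pd_traces_bc: dict[str, dict[str, np.ndarray]] = {}
    pd_traces_units: dict[str, dict[str, np.ndarray]] = {}
    ms_rates: dict[str, dict[str, np.ndarray]] = {}
    all_events: dict[tuple, list] = {}
    blink_sets = []
    reports = {}
    excluded = []
    time_axis = None

    for part in exp.participants:
        pid = part.participant
        try:
            rec = mask_fixation_breaks(part.recording, config.pupil)
            is_excl, frac = participant_excluded(rec, config.pupil)
            if is_excl:
                excluded.append({"participant": pid, "missing_fraction": frac})
                continue
            onsets = part.trials["onset_s"].to_list()
            conds = part.trials["condition"].to_list()
            channel = "pl" if config.pupil.eye == "left" else "pr"
            epochs = epoch_by_events(rec, onsets, window, channel=channel,
                                     conditions=conds, participant=pid)
            time_axis = epochs.time
            blink_sets.append(epochs)
            cleaned, report = clean_epochs(epochs, config.pupil)
            reports[pid] = report
            zscored, _ = zscore_participant(cleaned)
            bc = baseline_correct(zscored, config.pupil.baseline_window)
            pd_traces_units[pid] = condition_mean(cleaned)
            pd_traces_z[pid] = condition_mean(zscored)
            pd_traces_bc[pid] = condition_mean(bc)

            events = detect_microsaccades(rec, config.detection)
            onset_arr = np.asarray(onsets)
            per_trial = []
            for k, onset in enumerate(onsets):
                rel = [ev.onset - onset for ev in events
                       if window[0] <= ev.onset - onset < window[1]]
                per_trial.append(rel)
                all_events[(pid, conds[k], k)] = [
                    ev for ev in events if window[0] <= ev.onset - onset < window[1]]
            pulses = events_to_pulses(per_trial, epochs.time, conditions=conds,
                                      participant=pid)
            if config.patch_preonset:
                patch_seed = int(np.random.SeedSequence(
                    [config.seed, 1000 + int(pid[1:])]).generate_state(1)[0] % (2 ** 31))
                pulses = patch_preonset_gap(pulses, seed=patch_seed)
            ms_rates[pid] = {
                cond: rate_estimate(pulses.select(cond), config.alpha).rate
                for cond in conditions
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'participant' failed for {pid}") from exc

    if not pd_traces_z:
        raise RuntimeError("stage 'preprocess': no participants survived")

    results: dict = {"excluded": excluded, "reports": reports,
                     "time": time_axis}
    results["pd_group_z"] = group_condition_mean(list(pd_traces_z.values()))
    results["pd_group_bc"] = group_condition_mean(list(pd_traces_bc.values()))
    results["pd_group_units"] = group_condition_mean(list(pd_traces_units.values()))
    results["ms_group_rate"] = group_condition_mean(list(ms_rates.values()))
    t, incidence = blink_rate(blink_sets)
    results["blink_incidence"] = incidence

    summary: dict = {"n_participants": len(pd_traces_z),
                     "n_excluded": len(excluded)}
    if pair is not None:
        a, b = pair
        diff_pd = condition_difference(
            pd_traces_bc if config.baseline else pd_traces_z, pair, time_axis)
        diff_ms = condition_difference(ms_rates, pair, time_axis)
        mask_pd = _stage("bootstrap-pd", lambda: bootstrap_mask(
            diff_pd, config.bootstrap.n_iterations, config.bootstrap.criterion,
            seed=boot_seed_pd))
        mask_ms = _stage("bootstrap-ms", lambda: bootstrap_mask(
            diff_ms, config.bootstrap.n_iterations, config.bootstrap.criterion,
            seed=boot_seed_ms))
        results["pd_mask"] = mask_pd
        results["ms_mask"] = mask_ms
        results["pd_intervals"] = significant_intervals(mask_pd, min_length=50)
        results["ms_intervals"] = significant_intervals(mask_ms, min_length=50)
        write_mask_csv(mask_pd, out / "pd_mask.csv")
        write_mask_csv(mask_ms, out / "ms_mask.csv")

        lay = config.sim.trial_layout
        peak_window = (lay.sentence_onset, float(time_axis[-1]))
        for cond in pair:
            lat, ampl = pd_peak(time_axis, results["pd_group_bc"][cond], peak_window)
            summary[f"pd_peak_latency_{cond}"] = lat
            summary[f"pd_peak_amplitude_{cond}"] = ampl
        summary["pd_load_effect"] = pd_load_effect(
            time_axis, results["pd_group_bc"][a], results["pd_group_bc"][b],
            config.pupil.load_window)
        pre = time_axis < 0
        tonic_rows = np.array([
            (pd_traces_units[pid][a][pre] - pd_traces_units[pid][b][pre]).mean()
            for pid in pd_traces_units])
        summary["tonic_offset_mean"] = float(tonic_rows.mean())
        summary["tonic_offset_se"] = float(
            tonic_rows.std(ddof=1) / np.sqrt(tonic_rows.size))
        summary["ms_intervals"] = results["ms_intervals"]
        summary["pd_intervals"] = results["pd_intervals"]
    results["summary"] = summary

    _write_traces(out / "pd_traces.csv", time_axis, {
        "z": results["pd_group_z"], "baseline_corrected": results["pd_group_bc"],
        "units": results["pd_group_units"]})
    _write_traces(out / "ms_rates.csv", time_axis,
                  {"rate_hz": results["ms_group_rate"]})
    events_table(all_events, out / "ms_events.csv")
    pd.DataFrame({"time_s": time_axis, "incidence": incidence}).to_csv(
        out / "blink_incidence.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_participants": summary["n_participants"],
        "reports": reports,
        "stages": ["simulate", "mask", "epoch", "clean", "zscore", "baseline",
                   "detect", "rate", "bootstrap"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if config.make_figures and pair is not None:
        _render_figures(out, time_axis, results, pair)
    return results


def _stage(name: str, fn):
    try:
        return fn()
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed") from exc


def _write_traces(path, time, variants: dict) -> None:
    rows = []
    for variant, traces in variants.items():
        for cond, trace in traces.items():
            rows.append(pd.DataFrame({
                "time_s": time, "condition": cond, "variant": variant,
                "value": trace}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if callable(o):
            return getattr(o, "__name__", "callable")
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _render_figures(out: Path, time, results, pair) -> None:
    """PD trace pair, MS rate pair, and significance bars, from outputs only."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    for cond in pair:
        axes[0].plot(time, results["pd_group_bc"][cond], label=cond)
        axes[1].plot(time, results["ms_group_rate"][cond], label=cond)
    for ax, key, ylab in ((axes[0], "pd_mask", "pupil (z)"),
                          (axes[1], "ms_mask", "MS rate (events/s)")):
        mask = results.get(key)
        if mask is not None and mask.significant.any():
            y0 = ax.get_ylim()[0]
            ax.plot(time[mask.significant],
                    np.full(mask.significant.sum(), y0), ".", color="gray",
                    markersize=2)
        ax.set_ylabel(ylab)
        ax.legend(frameon=False)
    axes[1].set_xlabel("time re noise onset (s)")
    fig.tight_layout()
    fig.savefig(out / "overview.png", dpi=120)
    plt.close(fig)
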