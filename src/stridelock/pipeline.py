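"""End-to-end orchestration: bundles in, result artifacts on disk out."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cyclic, clusters, gait, saccades, timefreq
from .config import AnalysisConfig
from .io import Condition, RecordingBundle, read_eeg, read_tracking

log = logging.getLogger("stridelock")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, participant: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for participant "
                         f"{participant!r}: {cause}")
        self.stage = stage
        self.participant = participant


def process_tracking(bundle: RecordingBundle, config: AnalysisConfig) -> dict:
    """Saccade detection plus gait extraction for one session.

    Returns the saccade table (stride percentiles filled in), the stride
    table, per-participant binned series material and the retained step
    windows for the EEG stage.
    """
    rec = read_tracking(bundle.tracking_path)
    det = saccades.SaccadeDetectionParams(
        lambda_mult=config.lambda_mult, min_samples=config.min_samples,
        smooth_window=config.smooth_window, blink_jump=config.blink_jump)
    sacc = saccades.detect_saccades_in_recording(rec, det)

    tparams = gait.TroughParams(
        lowpass_hz=config.lowpass_hz, min_separation=config.min_separation,
        prominence_frac=config.prominence_frac,
        duration_bounds=config.duration_bounds)

    stride_rows = []
    percentiles = []
    step_windows = []
    sacc = sacc.copy()
    for trial in np.unique(rec.trial_id):
        sel = rec.trial_id == trial
        t = rec.time[sel]
        dropout = sum(t1 - t0 for t0, t1, _ in rec.dropouts
                      if t[0] <= t0 <= t[-1])
        try:
            steps = gait.detect_troughs(t, rec.head_pos[sel, 1], rec.rate,
                                        tparams, trial_id=int(trial))
        except ValueError:
            continue
        keep, reasons = gait.exclude_bad_trials(steps, dropout_s=dropout)
        for i, tt in enumerate(steps.trough_times):
            dur = steps.step_durations[i] if i < steps.n_steps else np.nan
            flag = ";".join(reasons) if not keep else (
                "bad step" if (i < steps.n_steps and steps.bad_steps[i]) else "")
            stride_rows.append((int(trial), float(tt), float(dur), flag))
        if not keep or not steps.usable:
            continue
        strides = gait.build_strides(steps, config.stride_convention)
        for i in range(steps.n_steps):
            if not steps.bad_steps[i]:
                step_windows.append((steps.trough_times[i],
                                     steps.trough_times[i + 1]))
        mask = sacc["trial"] == trial
        assigns, _ = gait.assign_phase(sacc.loc[mask, "onset_s"].to_numpy(),
                                       strides)
        percentiles.extend(a.percentile for a in assigns)
        step_pct, _ = gait.assign_step_phase(
            sacc.loc[mask, "onset_s"].to_numpy(), steps)
        sacc.loc[mask, "stride_pct"] = np.nan
        for a in assigns:
            hit = mask & np.isclose(sacc["onset_s"], a.event_time)
            sacc.loc[hit, "stride_pct"] = a.percentile
        sacc.loc[mask, "step_pct"] = step_pct

    strides_df = pd.DataFrame(stride_rows, columns=["trial", "trough_time",
                                                    "step_duration", "flag"])
    return {
        "saccades": sacc,
        "strides": strides_df,
        "stride_percentiles": np.array(percentiles),
        "step_windows": step_windows,
    }


def _binned_relative(percentiles: np.ndarray, n_bins: int) -> np.ndarray:
    series = cyclic.bin_phases(percentiles, n_bins)
    return cyclic.relative_change(series).values


def group_cyclic_stats(per_participant: dict, config: AnalysisConfig,
                       condition: str) -> dict:
    """Group scan + null, participant-level tests, prevalence, Rayleigh."""
    pids = sorted(per_participant)
    series = np.array([_binned_relative(per_participant[p], config.n_bins)
                       for p in pids])
    grid = config.frequency_grid
    group_mean = series.mean(axis=0)
    scan = cyclic.scan_frequencies(group_mean, grid)
    null = cyclic.permutation_null(
        series, config.n_permutations,
        seed=config.stage_seed("permutation_null"), grid=grid)
    group_test = cyclic.test_entrainment(scan, null, config.band)

    decisions = {}
    phases = []
    part_seed = config.stage_seed("participant_null").spawn(len(pids))
    for p, ss in zip(pids, part_seed):
        res = cyclic.participant_entrainment(
            series[pids.index(p)], config.n_permutations, seed=ss,
            grid=grid, band=config.band)
        decisions[p] = res["band_significant"]
        if res["band_significant"]:
            phases.append(cyclic.fit_fourier(series[pids.index(p)], 2.0).phase)

    k = sum(decisions.values())
    prev = cyclic.prevalence(k, len(pids), config.prevalence_alpha,
                             config.prevalence_beta)
    rayleigh = (cyclic.rayleigh_test(phases) if len(phases) >= 3 else None)

    return {
        "condition": condition,
        "grid": grid.tolist(),
        "r2": scan.r2.tolist(),
        "null_bound": null.bound95.tolist(),
        "best": {"w": scan.best.w, "a0": scan.best.a0, "a1": scan.best.a1,
                 "b1": scan.best.b1, "amplitude": scan.best.amplitude,
                 "phase": scan.best.phase, "r2": scan.best.r2},
        "band": list(config.band),
        "band_significant": group_test["band_significant"],
        "participant_significant": decisions,
        "prevalence": {"k": prev.k, "n": prev.n, "alpha": prev.alpha,
                       "beta": prev.beta, "map": prev.map,
                       "hpdi": list(prev.hpdi)},
        "rayleigh": (None if rayleigh is None else
                     {"n": rayleigh.n, "rbar": rayleigh.rbar,
                      "z": rayleigh.z, "p": rayleigh.p}),
        "phases": phases,
    }


def process_eeg(bundle: RecordingBundle, step_windows,
                config: AnalysisConfig, out_dir: Path) -> np.ndarray | None:
    """Gait-locked TF for one session; returns the freq x grid channel mean."""
    if not step_windows:
        return None
    eeg = read_eeg(bundle.eeg_path)
    pre = timefreq.preprocess(eeg)
    tf = timefreq.morlet_tf(pre.data, pre.rate, labels=pre.labels)
    onsets = [w[0] for w in step_windows]
    ends = [w[1] for w in step_windows]
    g = timefreq.gait_tf(tf, onsets, ends, raw=pre.data)
    np.savez(out_dir / f"{bundle.participant_id}_"
                       f"{bundle.condition.value}_gait_tf.npz",
             values=g.values, grid=g.grid, freqs=g.freqs,
             labels=np.array(g.labels))
    return np.nanmean(g.values, axis=0)   # channel mean -> freq x grid


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def run_pipeline(config: AnalysisConfig, out_dir) -> dict:
    """Run every stage for every bundle; write artifacts under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundles = [RecordingBundle(**b) for b in config.bundles]
    for b in bundles:
        b.validate_files()

    per_cond_pct = {}
    per_cond_maps = {}
    outputs = {"participants": [], "conditions": {}}
    for b in bundles:
        pid, cond = b.participant_id, b.condition.value
        try:
            res = process_tracking(b, config)
        except Exception as exc:             # noqa: BLE001
            raise PipelineError("tracking", pid, exc) from exc
        res["saccades"].to_csv(out_dir / f"{pid}_{cond}_saccades.tsv",
                               sep="\t", index=False)
        res["strides"].to_csv(out_dir / f"{pid}_{cond}_strides.tsv",
                              sep="\t", index=False)
        if res["stride_percentiles"].size:
            per_cond_pct.setdefault(cond, {})[pid] = res["stride_percentiles"]
        if config.run_eeg and b.condition is not Condition.STATIC:
            try:
                m = process_eeg(b, res["step_windows"], config, out_dir)
            except Exception as exc:         # noqa: BLE001
                raise PipelineError("eeg", pid, exc) from exc
            if m is not None:
                per_cond_maps.setdefault(cond, {})[pid] = m
        outputs["participants"].append(f"{pid}_{cond}")
        log.info("processed %s %s", pid, cond)

    for cond, d in per_cond_pct.items():
        try:
            stats = group_cyclic_stats(d, config, cond)
        except Exception as exc:             # noqa: BLE001
            raise PipelineError("cyclic_stats", cond, exc) from exc
        _write_json(out_dir / f"{cond}_scan.json", stats)
        outputs["conditions"].setdefault(cond, {})["scan"] = str(
            out_dir / f"{cond}_scan.json")

    for cond, d in per_cond_maps.items():
        if len(d) < 3:
            continue
        maps = np.array([d[p] for p in sorted(d)])
        cls = clusters.cluster_test(
            maps, config.cluster_permutations,
            seed=config.stage_seed("cluster_test"),
            p_thresh=config.cluster_p_thresh)
        grid = timefreq.GAIT_GRID
        freqs = timefreq.FREQS
        report = [{
            "sign": c.sign,
            "mass": c.mass,
            "size": c.size,
            "p_cluster": c.p_cluster,
            "peak_freq_hz": float(freqs[c.peak[0]]),
            "peak_pct": float(grid[c.peak[1]]),
            "freq_range_hz": [float(freqs[min(p[0] for p in c.pixels)]),
                              float(freqs[max(p[0] for p in c.pixels)])],
            "pct_range": [float(grid[min(p[1] for p in c.pixels)]),
                          float(grid[max(p[1] for p in c.pixels)])],
        } for c in cls]
        _write_json(out_dir / f"{cond}_clusters.json", report)
        outputs["conditions"].setdefault(cond, {})["clusters"] = str(
            out_dir / f"{cond}_clusters.json")

    _write_json(out_dir / "run_log.json", {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "outputs": outputs,
    })
    return outputs
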