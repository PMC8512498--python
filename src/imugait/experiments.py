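"""Reusable validation experiments on fully synthetic inputs.

Each experiment regenerates its data from a seed, runs the ordinary package
pipeline, and reports summary numbers; they back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import time

import numpy as np

from . import synthetic_gait as sg
from .agreement import bland_altman
from .lumbar import detect_events_lumbar, tilt_correct_to_vertical
from .metrics import match_events
from .pipeline import CellSpec, NoiseModel, StudyDesign, run_cell
from .shank import detect_events_shank_recording
from .temporal import assign_sides_lumbar, summarize_events


def event_recovery_experiment(
    seed: int,
    fs: float = 100.0,
    duration: float = 60.0,
    cohort: str = "YA",
    noise: bool = False,
    tolerance: float = 0.05,
) -> dict:
    """Both detectors against the scripted ground truth of one subject.

    Returns recall / median |error| per algorithm and event type, plus the
    wall-clock time of the full two-algorithm detection pass.
    """
    preset = sg.COHORT_PRESETS[cohort]
    script = sg.make_gait_script(preset, sg.single_bout_preset(duration), seed=seed)
    nm = NoiseModel() if noise else NoiseModel(0.0, 0.0, 0.0, 0.0)
    lum = sg.synthesize_lumbar_accel(script, fs, noise_sd=nm.accel_noise_sd,
                                     seed=seed + 1, tilt_deg=nm.tilt_deg)
    shanks = {
        side: sg.synthesize_shank_gyro(script, side, fs, noise_sd=nm.gyro_noise_sd,
                                       drift_rate=nm.gyro_drift_rate, seed=seed + 2)
        for side in ("L", "R")
    }

    t0 = time.perf_counter()
    vertical, _ = tilt_correct_to_vertical(lum)
    ev_lum = detect_events_lumbar(vertical, fs)
    ev_shank = {s: detect_events_shank_recording(r) for s, r in shanks.items()}
    runtime = time.perf_counter() - t0

    out = {"runtime_s": runtime, "n_strides": int(script.ic_left.size - 1
                                                  + script.ic_right.size - 1)}
    matches = {
        "a1_ic": match_events(ev_lum.ic_times, script.all_ic_times(), tolerance),
        "a1_fc": match_events(ev_lum.fc_times, script.all_fc_times(), tolerance),
    }
    for side in ("L", "R"):
        matches[f"a2_ic_{side}"] = match_events(
            ev_shank[side].ic_times, script.ic_times(side), tolerance)
        matches[f"a2_fc_{side}"] = match_events(
            ev_shank[side].fc_times, script.fc_times(side), tolerance)
    for name, m in matches.items():
        out[f"{name}_recall"] = m.recall
        out[f"{name}_median_abs_error_s"] = m.median_abs_error
    out["a2_ic_recall"] = min(out["a2_ic_L_recall"], out["a2_ic_R_recall"])
    out["a2_fc_recall"] = min(out["a2_fc_L_recall"], out["a2_fc_R_recall"])
    out["a2_ic_median_abs_error_s"] = max(
        out["a2_ic_L_median_abs_error_s"], out["a2_ic_R_median_abs_error_s"])
    out["a2_fc_median_abs_error_s"] = max(
        out["a2_fc_L_median_abs_error_s"], out["a2_fc_R_median_abs_error_s"])
    return out


def parameter_recovery_experiment(
    seed: int,
    n_subjects: int = 20,
    duration: float = 60.0,
    fs: float = 100.0,
    cohorts: tuple = ("YA", "OA", "PD"),
) -> dict:
    """Full detect-and-summarise recovery of the cohort timing parameters.

    Noise-free recordings; each subject uses the cohort-level preset directly
    (no between-subject sampling) so the generator values are the estimands.
    Reports, per cohort and algorithm, the pooled stride mean / within-subject
    variability and their standard errors.
    """
    results = {}
    rng = np.random.default_rng(seed)
    for cohort in cohorts:
        preset = sg.COHORT_PRESETS[cohort]
        means = {"a1": [], "a2": []}
        sds = {"a1": [], "a2": []}
        n_cycles = 0
        for _ in range(n_subjects):
            script = sg.make_gait_script(preset, sg.single_bout_preset(duration),
                                         seed=int(rng.integers(2**31)))
            lum = sg.synthesize_lumbar_accel(script, fs, noise_sd=0.0, tilt_deg=0.0)
            shanks = {
                s: sg.synthesize_shank_gyro(script, s, fs, noise_sd=0.0)
                for s in ("L", "R")
            }
            ev_shank = {s: detect_events_shank_recording(r)
                        for s, r in shanks.items()}
            ev_lum = detect_events_lumbar(lum.vertical_accel(), fs)
            lum_l, lum_r = assign_sides_lumbar(ev_lum, ev_shank["L"], ev_shank["R"])
            s1 = summarize_events(lum_l, lum_r)
            s2 = summarize_events(ev_shank["L"], ev_shank["R"])
            for label, s in (("a1", s1), ("a2", s2)):
                means[label].append(s.value("stride", "mean"))
                sds[label].append(s.value("stride", "variability"))
            n_cycles += s2.n_cycles
        cell = {
            "stride_mean_true": preset.stride_mean,
            "stride_sd_true": preset.stride_sd,
            "n_cycles": n_cycles,
            # strides overlap (consecutive ones share a step): sqrt(2) factor
            "se_mean": np.sqrt(2.0) * preset.stride_sd / np.sqrt(n_cycles),
            "se_sd": preset.stride_sd / np.sqrt(2.0 * n_cycles),
        }
        for label in ("a1", "a2"):
            cell[f"{label}_stride_mean"] = float(np.mean(means[label]))
            cell[f"{label}_stride_sd"] = float(np.mean(sds[label]))
        results[cohort] = cell
    return results


def mean_vs_variability_pattern_experiment(
    seed: int,
    n_replicates: int = 50,
    n_subjects: int = 31,
    fs: float = 100.0,
) -> dict:
    """Replicated indoor young-adult cells: is agreement highest for means?

    For each replicate, success = the mean-statistic ICC exceeds both the
    variability and asymmetry ICCs for at least 3 of the 4 temporal
    parameters.  Returns the success fraction and the average ICC per
    statistic.
    """
    successes = 0
    icc_sums = {"mean": 0.0, "variability": 0.0, "asymmetry": 0.0}
    n_icc = 0
    for rep in range(n_replicates):
        design = StudyDesign(
            cells=[CellSpec("YA", "indoor", n_subjects)],
            fs=fs,
            master_seed=seed + rep,
        )
        table, _ = run_cell(design.cells[0], design)
        wins = 0
        for param in ("stride", "stance", "swing", "step"):
            sub = table[table.parameter == param].set_index("statistic")["icc"]
            if sub["mean"] > sub["variability"] and sub["mean"] > sub["asymmetry"]:
                wins += 1
        if wins >= 3:
            successes += 1
        for stat in icc_sums:
            icc_sums[stat] += table[table.statistic == stat]["icc"].mean()
        n_icc += 1
    return {
        "success_fraction": successes / n_replicates,
        "n_replicates": n_replicates,
        **{f"avg_icc_{k}": v / n_icc for k, v in icc_sums.items()},
    }


def bland_altman_coverage_experiment(seed: int, n: int = 10_000) -> dict:
    """Fraction of Gaussian paired differences falling inside the LoA."""
    rng = np.random.default_rng(seed)
    base = rng.normal(1.1, 0.1, n)
    diff = rng.normal(0.01, 0.02, n)
    ba = bland_altman(base + diff, base)
    inside = np.mean((ba.diffs >= ba.loa_lower) & (ba.diffs <= ba.loa_upper))
    return {"coverage": float(inside), "n": n,
            "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff}
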