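"""End-to-end orchestration of the two analyses.

``run_experiment1`` takes per-subject scene/gaze/pupil data through
preprocessing, channel transform, gaze-window extraction, lag alignment,
per-subject correlation maps, group maps with FDR, dependent channel
comparisons and the upper-vs-lower test. ``run_experiment2`` takes trial
epochs through normalization, QC, PLRmin, the repeated-measures ANOVA and
the FDR-corrected difference scores.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .corrmap import (CorrelationMap, align, channel_pair_correlation,
                      estimate_lag, pixel_correlation_map, window_drive)
from .group_stats import (DependentComparison, GroupMapResult, fisher_z,
                          group_map, dependent_comparison_map,
                          upper_lower_test)
from .io_formats import FrameStack, RunConfig, write_map_bundle
from .plr import (COLORS, LOCATIONS, baseline_table,
                  difference_score_tests, qc_trials_and_subjects,
                  rm_anova_3x4, subject_plrmin_table)
from .preprocess import PreprocessParams, PupilTrace, preprocess_trace
from .scene_stats import (GammaParams, build_gaze_window_stack,
                          gamma_transform_fn, nan_fraction_map, rgb_to_cielab)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class SubjectData:
    """Raw inputs of one Experiment-1 subject."""

    subject: str
    frames: FrameStack
    gaze_xy: np.ndarray          # T x 2 screen px at the frame rate
    left: PupilTrace
    right: PupilTrace


@dataclass
class SubjectResult:
    subject: str
    cmap: CorrelationMap
    lag_ms: float
    lag_frames: int
    r_at_peak: float
    r23: dict                    # (chA, chB) -> per-cell channel-channel r
    upper_lower: dict            # channel index -> (t, p)
    n_time: int


@dataclass
class Exp1Result:
    config: RunConfig
    subjects: list
    group: dict                  # channel index -> GroupMapResult
    comparisons: dict            # (chA, chB) -> DependentComparison
    nan_fraction: np.ndarray
    lag_table: pd.DataFrame


def _frame_transform(config: RunConfig):
    """Per-frame channel transform for the configured channel space."""
    if config.channel_space == "cielab":
        return rgb_to_cielab
    return gamma_transform_fn(GammaParams(*config.gamma))


def analyze_subject(data: SubjectData, config: RunConfig,
                    params: PreprocessParams | None = None,
                    lag_mode: str = "fixed") -> SubjectResult:
    """Run the full Experiment-1 chain for one subject.

    ``lag_mode='fixed'`` shifts by ``config.lag_ms``; ``'auto'`` estimates
    the lag per subject by cross-correlating the pupil series with the mean
    window drive (most negative peak over the three channels).
    """
    params = params or PreprocessParams(target_fs=config.target_fs)
    try:
        trace = preprocess_trace(data.left, data.right, params)
    except Exception as exc:
        raise StageError("preprocess", str(exc)) from exc
    try:
        stack = build_gaze_window_stack(
            data.frames, data.gaze_xy, half=config.window_half,
            factor=config.downsample_factor,
            channel_space=config.channel_space,
            frame_transform=_frame_transform(config))
    except Exception as exc:
        raise StageError("scene_transform", str(exc)) from exc

    T = min(len(stack.data), len(trace.value))
    pupil = trace.value[:T]
    stack.data = stack.data[:T]

    try:
        if lag_mode == "auto":
            drives = window_drive(stack)
            best = None
            for ch in range(drives.shape[1]):
                est = estimate_lag(pupil, drives[:, ch], fs=config.target_fs,
                                   max_lag_ms=config.max_lag_ms)
                if best is None or est.r_at_peak < best.r_at_peak:
                    best = est
            lag_ms, lag_frames, r_peak = best.lag_ms, best.lag_frames, best.r_at_peak
        else:
            lag_frames = int(round(config.lag_ms * config.target_fs / 1000.0))
            lag_ms = lag_frames * 1000.0 / config.target_fs
            r_peak = np.nan
    except Exception as exc:
        raise StageError("lag_estimation", str(exc)) from exc

    try:
        pupil_aligned, data_trimmed = align(pupil, stack, lag_frames)
        cmap = pixel_correlation_map(pupil_aligned, data_trimmed,
                                     n_min=config.n_min,
                                     lag_frames=lag_frames)
    except Exception as exc:
        raise StageError("correlation_map", str(exc)) from exc

    r23 = {}
    for pair in ((0, 1), (0, 2), (1, 2)):
        r23[pair] = channel_pair_correlation(data_trimmed, *pair,
                                             n_min=config.n_min)
    upper_lower = {}
    for ch in range(cmap.r.shape[-1]):
        try:
            upper_lower[ch] = upper_lower_test(cmap.r[..., ch])
        except ValueError:
            upper_lower[ch] = (np.nan, np.nan)
    return SubjectResult(subject=data.subject, cmap=cmap, lag_ms=lag_ms,
                         lag_frames=lag_frames, r_at_peak=r_peak, r23=r23,
                         upper_lower=upper_lower,
                         n_time=len(pupil_aligned))


def run_experiment1(subjects: list, config: RunConfig,
                    params: PreprocessParams | None = None,
                    lag_mode: str = "fixed",
                    out_dir=None) -> Exp1Result:
    """Per-subject maps, group maps with FDR, channel comparisons and the
    per-subject upper-vs-lower tests; optionally writes a result bundle."""
    # subjects may be a lazily-evaluated iterable so that raw frame stacks
    # can be garbage-collected after each per-subject analysis
    results = [analyze_subject(s, config, params, lag_mode) for s in subjects]
    if not results:
        raise StageError("input", "no subjects supplied")

    n_ch = results[0].cmap.r.shape[-1]
    group = {}
    for ch in range(n_ch):
        z = np.stack([fisher_z(r.cmap.r[..., ch]) for r in results])
        group[ch] = group_map(z, q=config.fdr_q)

    comparisons = {}
    # (channel A, channel B): blue-red, green-red, blue-green
    for pair in ((2, 0), (1, 0), (2, 1)):
        a, b = pair
        r23_key = tuple(sorted(pair))
        maps_a = np.stack([r.cmap.r[..., a] for r in results])
        maps_b = np.stack([r.cmap.r[..., b] for r in results])
        r23 = np.stack([r.r23[r23_key] for r in results])
        n_time = np.array([r.n_time for r in results])
        comparisons[pair] = dependent_comparison_map(
            maps_a, maps_b, r23, n_time, q=config.fdr_q)

    # coverage: average per-subject NaN fraction of the r maps
    nan_frac = np.mean(np.stack([np.isnan(r.cmap.r[..., 0]) for r in results]),
                       axis=0)
    lag_table = pd.DataFrame(
        [{"subject": r.subject, "lag_ms": r.lag_ms,
          "lag_frames": r.lag_frames, "r_at_peak": r.r_at_peak}
         for r in results])

    result = Exp1Result(config=config, subjects=results, group=group,
                        comparisons=comparisons, nan_fraction=nan_frac,
                        lag_table=lag_table)
    if out_dir is not None:
        write_exp1_bundle(result, out_dir)
    return result


def iter_exp1_subjects(n_subjects: int = 34, seed: int = 0,
                       scene_cfg=None, gaze_cfg=None, pupil_cfg=None,
                       truth_sink: list | None = None):
    """Lazily generate synthetic Experiment-1 subjects one at a time.

    Yields SubjectData so that large frame stacks can be released after each
    per-subject analysis; ground-truth records are appended to
    ``truth_sink`` when given. The same eye is supplied for left and right,
    so eye selection is a tie.
    """
    from .simulate import (GazeSimConfig, PupilSimConfig, SceneSimConfig,
                           simulate_gaze, simulate_pupil_from_scene,
                           simulate_scene)

    scene_cfg = scene_cfg or SceneSimConfig()
    gaze_cfg = gaze_cfg or GazeSimConfig()
    pupil_cfg = pupil_cfg or PupilSimConfig(window_half=70, factor=2)
    rng = np.random.default_rng(seed)
    for s in range(n_subjects):
        s_seed, g_seed, p_seed = (int(x) for x in rng.integers(2**31, size=3))
        frames = simulate_scene(replace(scene_cfg, seed=s_seed))
        gaze = simulate_gaze(len(frames), (scene_cfg.H, scene_cfg.W),
                             scene_cfg.horizon_row,
                             replace(gaze_cfg, seed=g_seed))
        trace, truth = simulate_pupil_from_scene(
            frames, gaze, replace(pupil_cfg, seed=p_seed))
        if truth_sink is not None:
            truth_sink.append(truth)
        yield SubjectData(subject=f"sub{s:02d}", frames=frames,
                          gaze_xy=gaze, left=trace, right=trace)


def simulate_exp1_subjects(n_subjects: int = 34, seed: int = 0,
                           scene_cfg=None, gaze_cfg=None, pupil_cfg=None,
                           ) -> tuple[list, list]:
    """Materialized cohort of synthetic Experiment-1 subjects (small runs);
    for long recordings prefer :func:`iter_exp1_subjects`."""
    truths: list = []
    subjects = list(iter_exp1_subjects(n_subjects, seed, scene_cfg, gaze_cfg,
                                       pupil_cfg, truth_sink=truths))
    return subjects, truths


CHANNEL_NAMES = {"rgb_lum": ("red", "green", "blue"),
                 "cielab": ("L", "a", "b")}


def write_exp1_bundle(result: Exp1Result, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = CHANNEL_NAMES[result.config.channel_space]
    manifest = {
        "version": __version__,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config_hash": hashlib.sha256(
            json.dumps(result.config.__dict__, sort_keys=True,
                       default=str).encode()).hexdigest()[:16],
        "outputs": [],
    }
    for ch, g in result.group.items():
        maps = {f"group_{names[ch]}_mean_z": g.mean_z,
                f"group_{names[ch]}_t": g.t,
                f"group_{names[ch]}_p": g.p,
                f"group_{names[ch]}_qmask": g.q_mask.astype(float)}
        files = write_map_bundle(maps, out_dir, metadata={
            "statistic": "one_sample_t", "q": g.q,
            "channel": names[ch]})
        manifest["outputs"] += [str(f) for f in files]
    for (a, b), comp in result.comparisons.items():
        key = f"{names[a]}_vs_{names[b]}"
        maps = {f"compare_{key}_t": comp.group_t,
                f"compare_{key}_qmask": comp.q_mask.astype(float)}
        files = write_map_bundle(maps, out_dir, metadata={
            "statistic": comp.method, "q": comp.q})
        manifest["outputs"] += [str(f) for f in files]
    write_map_bundle({"nan_fraction": result.nan_fraction}, out_dir,
                     metadata={"statistic": "nan_fraction"})
    lag_path = out_dir / "lag_table.csv"
    result.lag_table.to_csv(lag_path, index=False)
    manifest["outputs"].append(str(lag_path))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


@dataclass
class Exp2Result:
    qc: pd.DataFrame
    plr_min: np.ndarray          # included subjects x 3 x 4
    included_subjects: list
    anova: pd.DataFrame
    diff_scores: pd.DataFrame
    baselines: np.ndarray


def run_experiment2(subjects: list, q: float = 0.05,
                    out_dir=None) -> Exp2Result:
    """QC, PLRmin extraction, ANOVA and difference scores for a set of
    Experiment-2 subjects."""
    if not subjects:
        raise StageError("input", "empty trial set")
    qc_rows = []
    tables, bases, included = [], [], []
    for sub in subjects:
        kept, ok = qc_trials_and_subjects(sub)
        qc_rows.append({"subject": sub.subject, "n_trials": len(sub.samples),
                        "n_valid": len(kept), "included": ok})
        if ok:
            tables.append(subject_plrmin_table(sub))
            bases.append(baseline_table(sub))
            included.append(sub.subject)
    qc = pd.DataFrame(qc_rows)
    if not tables:
        raise StageError("qc", "all subjects excluded; see QC report:\n"
                         + qc.to_string(index=False))
    plr = np.stack(tables)
    anova = rm_anova_3x4(plr)
    diffs = difference_score_tests(plr, q=q)
    result = Exp2Result(qc=qc, plr_min=plr, included_subjects=included,
                        anova=anova, diff_scores=diffs,
                        baselines=np.stack(bases))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        qc.to_csv(out_dir / "qc_report.csv", index=False)
        anova.to_csv(out_dir / "anova_table.csv", index=False)
        diffs.to_csv(out_dir / "difference_scores.csv", index=False)
        rows = []
        for s, tab in zip(included, plr):
            for i, c in enumerate(COLORS):
                for j, l in enumerate(LOCATIONS):
                    rows.append({"subject": s, "color": c, "location": l,
                                 "plr_min": tab[i, j]})
        pd.DataFrame(rows).to_csv(out_dir / "plrmin_table.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps({
            "version": __version__, "n_included": len(included),
            "fdr_q": q}, indent=2))
    return result
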