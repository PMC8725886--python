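"""Synthetic scenes, gaze trajectories, pupil traces and trial sets with
known ground truth, so every pipeline stage has a parameter-recovery test.

The scene is a piecewise-constant sky/terrain layout (blue-dominant above a
horizon row, red/green-dominant below) whose channel intensities fluctuate
as AR(1) processes. The pupil is driven by a spatially weighted sum of the
gamma-transformed gaze window, passed through a gamma-family impulse
response, inverted (brighter -> smaller), delayed, and contaminated with
Gaussian noise, blinks (with partial-closure ramps) and spike artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import FrameStack
from .preprocess import PupilTrace
from .plr import COLORS, LOCATIONS, Exp2Subject, epoch_time_ms
from .scene_stats import (GammaParams, build_gaze_window_stack,
                          gamma_transform_fn)


# ---------------------------------------------------------------------------
# Scene
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSimConfig:
    H: int = 200
    W: int = 280
    horizon_row: int = 100
    sky_rgb: tuple = (90.0, 120.0, 190.0)       # blue-dominant mean
    terrain_rgb: tuple = (150.0, 110.0, 60.0)   # red/green-dominant mean
    ar_phi: float = 0.6
    ar_sigma: float = 14.0       # per-channel fluctuation SD (intensity codes)
    patch_px: int = 20           # side of independently fluctuating patches
    patch_sigma: float = 6.0     # per-patch AR(1) SD on top of the region mean
    pixel_noise_sigma: float = 2.0
    T: int = 600
    fs: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.horizon_row < self.H:
            raise ValueError("horizon_row must lie strictly inside the frame")
        if abs(self.ar_phi) >= 1:
            raise ValueError("|ar_phi| must be < 1")
        if self.T < 1 or self.H < 1 or self.W < 1:
            raise ValueError("T, H, W must be positive")
        if self.patch_px < 1:
            raise ValueError("patch_px must be positive")


def _ar1(T: int, phi: float, sigma: float, rng: np.random.Generator,
         ncols: int) -> np.ndarray:
    """T x ncols stationary AR(1) with innovation scaled to marginal sigma."""
    innov_sd = sigma * np.sqrt(1 - phi**2)
    x = np.empty((T, ncols))
    x[0] = rng.normal(0, sigma, ncols)
    eps = rng.normal(0, innov_sd, (T - 1, ncols)) if T > 1 else None
    for t in range(1, T):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def simulate_scene(cfg: SceneSimConfig = SceneSimConfig()) -> FrameStack:
    """Sky/terrain frame stack with AR(1) channel fluctuations.

    Sky pixels share one per-channel fluctuation process and terrain pixels
    an independent one; small iid pixel noise is added on top. Deterministic
    given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    sky_fluct = _ar1(cfg.T, cfg.ar_phi, cfg.ar_sigma, rng, 3)
    ter_fluct = _ar1(cfg.T, cfg.ar_phi, cfg.ar_sigma, rng, 3)
    # region mean per row: sky above the horizon, terrain below
    region = np.empty((cfg.T, cfg.H, 3))
    region[:, :cfg.horizon_row] = (np.asarray(cfg.sky_rgb)
                                   + sky_fluct)[:, None, :]
    region[:, cfg.horizon_row:] = (np.asarray(cfg.terrain_rgb)
                                   + ter_fluct)[:, None, :]
    npr = -(-cfg.H // cfg.patch_px)
    npc = -(-cfg.W // cfg.patch_px)
    if cfg.patch_sigma > 0:
        patch = _ar1(cfg.T, cfg.ar_phi, cfg.patch_sigma, rng,
                     npr * npc * 3).reshape(cfg.T, npr, npc, 3)
    else:
        patch = None
    frames = np.empty((cfg.T, cfg.H, cfg.W, 3), np.uint8)
    chunk = max(1, int(5e7 // (cfg.H * cfg.W * 3)))  # bound float temporaries
    for t0 in range(0, cfg.T, chunk):
        t1 = min(t0 + chunk, cfg.T)
        if cfg.pixel_noise_sigma > 0:
            block = np.broadcast_to(region[t0:t1, :, None, :],
                                    (t1 - t0, cfg.H, cfg.W, 3)).copy()
            if patch is not None:
                block += np.repeat(np.repeat(patch[t0:t1], cfg.patch_px, 1),
                                   cfg.patch_px, 2)[:, :cfg.H, :cfg.W]
            block += rng.normal(0, cfg.pixel_noise_sigma, block.shape)
            np.clip(np.round(block, out=block), 0, 255, out=block)
            frames[t0:t1] = block.astype(np.uint8)
        else:
            # values are constant within a patch column, so quantize at
            # row x patch-column resolution and repeat the bytes
            cols = np.broadcast_to(region[t0:t1, :, None, :],
                                   (t1 - t0, cfg.H, npc, 3)).copy()
            if patch is not None:
                cols += np.repeat(patch[t0:t1], cfg.patch_px,
                                  1)[:, :cfg.H]
            np.clip(np.round(cols, out=cols), 0, 255, out=cols)
            frames[t0:t1] = np.repeat(cols.astype(np.uint8), cfg.patch_px,
                                      2)[:, :, :cfg.W]
    ts = np.arange(cfg.T) / cfg.fs
    return FrameStack(frames=frames, timestamps=ts, fs=cfg.fs)


# ---------------------------------------------------------------------------
# Gaze
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GazeSimConfig:
    step_sd: float = 6.0          # horizontal random-walk step SD in px
    step_sd_y: float | None = None  # vertical step SD; None -> same as step_sd
    pull: float = 0.05            # mean-reversion toward the anchor point
    dropout_rate_per_min: float = 0.0
    dropout_ms: tuple = (200.0, 800.0)
    seed: int = 0


def simulate_gaze(T: int, screen_hw: tuple, horizon_row: int,
                  cfg: GazeSimConfig = GazeSimConfig()) -> np.ndarray:
    """T x 2 gaze trajectory (x, y) hovering near the horizon row.

    A mean-reverting random walk anchored at (screen centre x, horizon row),
    clamped to the screen, with optional NaN dropout episodes.
    """
    H, W = screen_hw
    rng = np.random.default_rng(cfg.seed)
    anchor = np.array([W / 2.0, float(horizon_row)])
    sd = np.array([cfg.step_sd,
                   cfg.step_sd if cfg.step_sd_y is None else cfg.step_sd_y])
    g = np.empty((T, 2))
    pos = anchor.copy()
    for t in range(T):
        pos = pos + cfg.pull * (anchor - pos) + rng.normal(0, 1, 2) * sd
        pos[0] = np.clip(pos[0], 0, W - 1)
        pos[1] = np.clip(pos[1], 0, H - 1)
        g[t] = pos
    if cfg.dropout_rate_per_min > 0:
        fs = 12.0
        n_drop = rng.poisson(cfg.dropout_rate_per_min * T / fs / 60.0)
        for _ in range(n_drop):
            dur = rng.uniform(*cfg.dropout_ms)
            k = max(1, int(round(dur * fs / 1000.0)))
            start = rng.integers(0, max(1, T - k))
            g[start:start + k] = np.nan
    return g


# ---------------------------------------------------------------------------
# Pupil from scene
# ---------------------------------------------------------------------------

def gamma_irf(t_ms: np.ndarray, n: float = 10.1,
              t_max_ms: float = 930.0) -> np.ndarray:
    """Gamma-family pupil impulse response h(t) = t^n exp(-n t / t_max).

    Peaks at ``t_max_ms``; zero for t < 0. Unnormalized.
    """
    t = np.asarray(t_ms, float)
    with np.errstate(invalid="ignore"):
        h = np.where(t > 0, (t / t_max_ms) ** n * np.exp(n * (1 - t / t_max_ms)),
                     0.0)
    return h


@dataclass(frozen=True)
class PupilSimConfig:
    """Generative parameters of the scene-driven pupil trace.

    ``w_map`` is an n x n x 3 non-negative spatial kernel over window cells
    (normalized internally). ``lag_ms`` is the peak latency of the pupil
    response to the drive: the impulse response is time-shifted so its peak
    sits at ``lag_ms``, which is what a cross-correlation peak recovers.
    """

    w_map: np.ndarray = None
    lag_ms: float = 500.0
    irf_n: float = 10.1
    irf_tmax_ms: float = 930.0
    noise_sigma: float = 8.0       # a.u. at the output rate (marginal SD)
    noise_phi: float = 0.6         # AR(1) smoothness of measurement noise
    gain: float = 60.0             # a.u. per SD of drive
    baseline: float = 900.0        # a.u.
    blink_rate_per_min: float = 6.0
    spike_rate_per_min: float = 4.0
    spike_amp: float = 200.0
    out_fs: float = 300.0
    window_half: int = 350
    factor: int = 10
    gamma: GammaParams = field(default_factory=GammaParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w_map is not None:
            w = np.asarray(self.w_map, float)
            if w.ndim != 3 or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("w_map must be a non-negative n x n x 3 kernel")
        if self.irf_tmax_ms <= 0 or self.lag_ms < 0:
            raise ValueError("need irf_tmax_ms > 0 and lag_ms >= 0")


def upper_field_kernel(n: int = 70, channel: int = 2) -> np.ndarray:
    """Uniform spatial kernel over the upper half of one channel (default
    blue), zero elsewhere; the canonical blue-sky generative kernel."""
    w = np.zeros((n, n, 3))
    w[: n // 2, :, channel] = 1.0
    return w / w.sum()


def _effective_kernel(cfg: PupilSimConfig, fs: float):
    """Discrete drive->pupil kernel at the scene rate, with its peak at
    cfg.lag_ms; returns (kernel, delay_frames)."""
    dt_ms = 1000.0 / fs
    if cfg.lag_ms >= cfg.irf_tmax_ms:
        shift_ms = 0.0
        delay_frames = int(round((cfg.lag_ms - cfg.irf_tmax_ms) / dt_ms))
    else:
        shift_ms = cfg.irf_tmax_ms - cfg.lag_ms
        delay_frames = 0
    support_ms = cfg.irf_tmax_ms * 4.0
    t = np.arange(0.0, support_ms, dt_ms) + shift_ms
    h = gamma_irf(t, cfg.irf_n, cfg.irf_tmax_ms)
    if h.sum() <= 0:
        h = np.zeros_like(h)
        h[0] = 1.0
    return h / h.sum(), delay_frames


def simulate_pupil_from_scene(frames: FrameStack, gaze_xy: np.ndarray,
                              cfg: PupilSimConfig = PupilSimConfig()):
    """Generate a contaminated pupil trace from a scene and gaze trajectory.

    Returns ``(trace, truth)`` where ``trace`` is a PupilTrace at
    ``cfg.out_fs`` and ``truth`` records everything needed to score
    recovery: the kernel, the generative lag (in ms and in frames at the
    scene rate), the clean 12 Hz pupil series, the drive series, and the
    inserted blink/spike sample indices.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = frames.fs
    stack = build_gaze_window_stack(
        frames, gaze_xy, half=cfg.window_half, factor=cfg.factor,
        frame_transform=gamma_transform_fn(cfg.gamma))
    n = stack.data.shape[1]
    w = cfg.w_map if cfg.w_map is not None else upper_field_kernel(n)
    w = np.asarray(w, float)
    w = w / w.sum()
    if w.shape != stack.data.shape[1:]:
        raise ValueError(f"w_map shape {w.shape} does not match window cells "
                         f"{stack.data.shape[1:]}")

    if not np.isnan(stack.data).any():
        drive = np.einsum("tijc,ijc->t", stack.data, w)
    else:
        cell_ok = np.isfinite(stack.data)
        w_valid = (cell_ok * w).sum(axis=(1, 2, 3))
        with np.errstate(invalid="ignore", divide="ignore"):
            drive = np.nansum(stack.data * w, axis=(1, 2, 3)) / w_valid
        drive[w_valid <= 0] = np.nan
    d = drive.copy()
    finite = np.isfinite(d)
    d[~finite] = np.interp(np.flatnonzero(~finite), np.flatnonzero(finite),
                           d[finite]) if finite.any() else 0.0
    d_z = (d - d.mean()) / (d.std() if d.std() > 0 else 1.0)

    kernel, delay = _effective_kernel(cfg, fs)
    resp = np.convolve(d_z, kernel)[: len(d_z)]
    if delay:
        resp = np.concatenate([np.full(delay, resp[0]), resp[:-delay]])
    clean_12 = cfg.baseline - cfg.gain * resp

    rep = int(round(cfg.out_fs / fs))
    value = np.repeat(clean_12, rep)
    n_out = len(value)
    if cfg.noise_sigma > 0:
        from scipy.signal import lfilter
        innov = rng.normal(0, cfg.noise_sigma * np.sqrt(1 - cfg.noise_phi**2),
                           n_out)
        value = value + lfilter([1.0], [1.0, -cfg.noise_phi], innov)

    minutes = n_out / cfg.out_fs / 60.0
    # a positive rate guarantees at least one artifact: these traces are
    # contaminated by contract, however short
    spike_idx = []
    n_spikes = rng.poisson(cfg.spike_rate_per_min * minutes)
    if cfg.spike_rate_per_min > 0:
        n_spikes = max(1, n_spikes)
    for _ in range(n_spikes):
        i = int(rng.integers(1, n_out - 1))
        value[i] += rng.choice([-1.0, 1.0]) * cfg.spike_amp
        spike_idx.append(i)

    blink_intervals = []
    n_blinks = rng.poisson(cfg.blink_rate_per_min * minutes)
    if cfg.blink_rate_per_min > 0:
        n_blinks = max(1, n_blinks)
    min_gap = int(round(0.600 * cfg.out_fs))  # keep blinks well separated
    for _ in range(n_blinks):
        dur_ms = rng.uniform(100.0, 400.0)
        k = int(round(dur_ms * cfg.out_fs / 1000.0))
        ramp = max(1, int(round(0.020 * cfg.out_fs)))  # 20 ms closure ramps
        start = int(rng.integers(ramp, max(ramp + 1, n_out - k - ramp)))
        if any(start - min_gap < e and start + k + min_gap > s
               for s, e in blink_intervals):
            continue  # overlapping draw; keep blinks isolated
        drop = cfg.baseline * 0.4
        value[start - ramp:start] -= drop * np.linspace(0, 1, ramp, endpoint=False)
        value[start:start + k] = np.nan
        end = min(start + k, n_out)
        r2 = min(ramp, n_out - end)
        value[end:end + r2] -= drop * np.linspace(1, 0, r2, endpoint=False)
        blink_intervals.append((start, end))

    trace = PupilTrace.from_values(value, fs=cfg.out_fs)
    truth = {
        "w_map": w,
        "lag_ms": cfg.lag_ms,
        "lag_frames": int(round(cfg.lag_ms * fs / 1000.0)),
        "clean_pupil_12hz": clean_12,
        "drive": drive,
        "blink_intervals": blink_intervals,
        "spike_indices": spike_idx,
        "kernel": kernel,
        "stack_shape": stack.data.shape,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# Experiment-2 trial sets
# ---------------------------------------------------------------------------

def build_exp2_design(colors=COLORS, locations=LOCATIONS, reps: int = 5,
                      seed: int | None = None) -> pd.DataFrame:
    """Fully crossed, replicated and shuffled trial table.

    The canonical design (3 colors x 4 locations x 5 reps) has 60 rows and
    12 distinct conditions with equal counts.
    """
    rows = [(c, l) for c in colors for l in locations for _ in range(reps)]
    df = pd.DataFrame(rows, columns=["color", "location"])
    if seed is not None:
        df = df.sample(frac=1.0, random_state=seed).reset_index(drop=True)
    df.insert(0, "trial", np.arange(len(df)))
    df["condition"] = df["color"] + "_" + df["location"]
    return df


def default_exp2_amplitudes() -> np.ndarray:
    """3 x 4 PLRmin means (%), colors x locations: blue stronger overall and
    an extra constriction for blue-on-top."""
    amp = np.empty((3, 4))
    amp[COLORS.index("red")] = -37.7
    amp[COLORS.index("green")] = -37.2
    amp[COLORS.index("blue")] = -44.3
    amp[COLORS.index("blue"), LOCATIONS.index("top")] += -4.0
    return amp


@dataclass(frozen=True)
class Exp2SimConfig:
    amplitudes: np.ndarray = None   # 3 x 4 mean PLRmin (%), colors x locations
    between_sd: float = 3.0         # between-subject amplitude SD (%)
    within_sd: float = 5.0          # trial-to-trial amplitude SD (%)
    noise_sd: float = 4.0           # sample noise, device a.u.
    baseline_mean: float = 900.0    # a.u.
    baseline_sd: float = 150.0      # between-subject baseline SD
    blink_prob: float = 0.1         # per-trial probability of a QC-voiding blink
    n_subjects: int = 15
    reps: int = 5
    irf_n: float = 10.1
    irf_tmax_ms: float = 930.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0 <= self.blink_prob <= 1:
            raise ValueError("blink_prob must lie in [0, 1]")
        if self.amplitudes is not None:
            a = np.asarray(self.amplitudes, float)
            if a.shape != (len(COLORS), len(LOCATIONS)):
                raise ValueError("amplitudes must be 3 x 4 (colors x locations)")


def simulate_exp2(cfg: Exp2SimConfig = Exp2SimConfig()):
    """Simulate Experiment-2 subjects.

    Each trial epoch is baseline * (1 + A_trial/100 * h(t)) + noise, with
    h the gamma-family impulse response normalized to unit peak (so the
    noiseless PLRmin equals A exactly) and A_trial drawn around the
    condition mean with subject and trial variability. Blink-contaminated
    trials get a NaN run inside the (0, 1500] ms QC window.

    Returns ``(subjects, truth)`` where ``subjects`` is a list of
    Exp2Subject and ``truth`` holds the amplitude table and per-subject
    offsets.
    """
    rng = np.random.default_rng(cfg.seed)
    amp = np.asarray(cfg.amplitudes if cfg.amplitudes is not None
                     else default_exp2_amplitudes(), float)
    t_ms = epoch_time_ms()
    h = gamma_irf(t_ms, cfg.irf_n, cfg.irf_tmax_ms)
    h = h / h.max()
    subjects = []
    offsets = np.empty(cfg.n_subjects)
    for s in range(cfg.n_subjects):
        design = build_exp2_design(reps=cfg.reps,
                                   seed=int(rng.integers(2**31)))
        colors = design["color"].to_numpy()
        locations = design["location"].to_numpy()
        ci = np.array([COLORS.index(c) for c in colors])
        li = np.array([LOCATIONS.index(l) for l in locations])
        offsets[s] = rng.normal(0, cfg.between_sd)
        baseline = max(50.0, cfg.baseline_mean + rng.normal(0, cfg.baseline_sd))
        a_trial = amp[ci, li] + offsets[s] + rng.normal(
            0, cfg.within_sd, len(design))
        samples = baseline * (1.0 + a_trial[:, None] / 100.0 * h[None, :])
        if cfg.noise_sd > 0:
            samples = samples + rng.normal(0, cfg.noise_sd, samples.shape)
        if cfg.blink_prob > 0:
            blinked = rng.random(len(design)) < cfg.blink_prob
            for i in np.flatnonzero(blinked):
                start_ms = rng.uniform(50, 1200)
                dur_ms = rng.uniform(100, 300)
                win = (t_ms >= start_ms) & (t_ms < start_ms + dur_ms)
                samples[i, win] = np.nan
        subjects.append(Exp2Subject(subject=f"sub{s:02d}", samples=samples,
                                    t_ms=t_ms, colors=colors,
                                    locations=locations))
    truth = {"amplitudes": amp, "subject_offsets": offsets,
             "irf_peak_ms": cfg.irf_tmax_ms}
    return subjects, truth
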