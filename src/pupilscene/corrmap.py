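"""Lag estimation, series alignment, and per-subject pixel-wise correlation
maps between pupil size and gaze-window channel intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scene_stats import GazeWindowStack


@dataclass(frozen=True)
class LagEstimate:
    lag_ms: float
    lag_frames: int
    r_at_peak: float
    low_confidence: bool  # |r| < 0.1 at the peak


@dataclass
class CorrelationMap:
    """Per-cell Pearson r between pupil size and window intensities.

    ``r`` is n x n x C (NaN where coverage or variance is insufficient),
    ``n_eff`` the per-cell paired-sample count (per channel).
    """

    r: np.ndarray
    n_eff: np.ndarray
    lag_frames: int
    channel_space: str


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def estimate_lag(pupil: np.ndarray, drive: np.ndarray, fs: float = 12.0,
                 max_lag_ms: float = 2000.0, min_pairs: int = 50,
                 mode: str = "most_negative") -> LagEstimate:
    """Cross-correlate pupil size against a scene drive over non-negative lags.

    Evaluates Pearson r between drive(t) and pupil(t + tau) for tau in
    0..max_lag frames and returns the lag at the peak. Because luminance and
    pupil size are inversely related the default peak is the most negative
    r; ``mode='max_abs'`` picks the largest magnitude instead. A peak with
    |r| < 0.1 is flagged low-confidence.
    """
    pupil = np.asarray(pupil, float)
    drive = np.asarray(drive, float)
    if pupil.shape != drive.shape:
        raise ValueError("pupil and drive must have equal length")
    for name, s in (("pupil", pupil), ("drive", drive)):
        vals = s[np.isfinite(s)]
        if len(vals) == 0 or vals.std() == 0:
            raise ValueError(f"{name} series is constant or empty")
    if mode not in ("most_negative", "max_abs"):
        raise ValueError("mode must be 'most_negative' or 'max_abs'")

    max_frames = int(round(max_lag_ms * fs / 1000.0))
    max_frames = min(max_frames, len(pupil) - 2)
    rs = np.full(max_frames + 1, np.nan)
    for tau in range(max_frames + 1):
        d = drive[:len(drive) - tau] if tau else drive
        p = pupil[tau:]
        ok = np.isfinite(d) & np.isfinite(p)
        if ok.sum() < min_pairs:
            raise ValueError(
                f"fewer than {min_pairs} valid pairs at lag {tau} frames")
        rs[tau] = _pearson(d, p)
    if np.all(np.isnan(rs)):
        raise ValueError("no lag produced a defined correlation")
    if mode == "most_negative":
        tau_star = int(np.nanargmin(rs))
    else:
        tau_star = int(np.nanargmax(np.abs(rs)))
    r = float(rs[tau_star])
    return LagEstimate(lag_ms=tau_star / fs * 1000.0, lag_frames=tau_star,
                       r_at_peak=r, low_confidence=abs(r) < 0.1)


def shift_pupil(pupil: np.ndarray, lag_frames: int) -> np.ndarray:
    """Advance the pupil series by ``lag_frames`` so pupil(t+lag) pairs with
    scene(t); the returned series has length len(pupil) - lag_frames and the
    caller trims the scene stack to match."""
    pupil = np.asarray(pupil, float)
    if lag_frames < 0:
        raise ValueError("lag_frames must be non-negative")
    if lag_frames >= len(pupil):
        raise ValueError("lag exceeds series length")
    return pupil[lag_frames:] if lag_frames else pupil.copy()


def align(pupil: np.ndarray, stack: GazeWindowStack,
          lag_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Pair pupil(t+lag) with window(t); returns (pupil_aligned, data_trimmed)."""
    p = shift_pupil(pupil, lag_frames)
    data = stack.data[:len(stack.data) - lag_frames] if lag_frames else stack.data
    return p, data


def pixel_correlation_map(pupil_aligned: np.ndarray, windows,
                          n_min: int | None = None,
                          lag_frames: int = 0) -> CorrelationMap:
    """Pairwise-complete Pearson r between the pupil series and every window
    cell and channel.

    Cells with fewer than ``n_min`` paired samples, or with zero variance,
    are NaN. ``n_min`` defaults to max(100, 5% of T).
    """
    data = windows.data if isinstance(windows, GazeWindowStack) else np.asarray(windows, float)
    channel_space = windows.channel_space if isinstance(windows, GazeWindowStack) else "unknown"
    pupil = np.asarray(pupil_aligned, float)
    T = data.shape[0]
    if len(pupil) != T:
        raise ValueError("pupil length must equal the window stack length")
    if n_min is None:
        n_min = max(100, int(round(0.05 * T)))

    p_ok = np.isfinite(pupil)
    if p_ok.all() and not np.isnan(data).any():
        # complete-data fast path: single-pass sums via einsum
        n = np.full(data.shape[1:], float(T))
        sx = data.sum(axis=0)
        sy = np.full(data.shape[1:], pupil.sum())
        sxx = np.einsum("t...,t...->...", data, data)
        syy = np.full(data.shape[1:], float(pupil @ pupil))
        sxy = np.einsum("t,t...->...", pupil, data)
    else:
        p = pupil[:, None, None, None]
        ok = np.isfinite(data) & np.isfinite(p)
        x = np.where(ok, data, 0.0)
        y = np.where(ok, p, 0.0)
        n = ok.sum(axis=0).astype(float)
        sx = x.sum(axis=0)
        sy = y.sum(axis=0)
        sxx = (x * x).sum(axis=0)
        syy = (y * y).sum(axis=0)
        sxy = (x * y).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r = cov / np.sqrt(varx * vary)
        # numeric guard: zero variance shows up as tiny or negative var
        tol = 1e-12 * np.maximum(sxx, 1.0) * np.maximum(n, 1.0)
        r[(varx <= tol) | (vary <= tol)] = np.nan
    r[n < n_min] = np.nan
    if np.all(np.isnan(r)):
        raise ValueError("correlation map is entirely NaN")
    return CorrelationMap(r=np.clip(r, -1.0, 1.0), n_eff=n.astype(int),
                          lag_frames=lag_frames, channel_space=channel_space)


def channel_pair_correlation(windows, ch_a: int, ch_b: int,
                             n_min: int | None = None) -> np.ndarray:
    """Per-cell Pearson r between two channels of the same window stack
    (the r23 term of a dependent-correlation comparison)."""
    data = windows.data if isinstance(windows, GazeWindowStack) else np.asarray(windows, float)
    a = data[..., ch_a]
    b = data[..., ch_b]
    T = a.shape[0]
    if n_min is None:
        n_min = max(100, int(round(0.05 * T)))
    if not (np.isnan(a).any() or np.isnan(b).any()):
        n = np.full(a.shape[1:], float(T))
        sx, sy = a.sum(axis=0), b.sum(axis=0)
        sxx = np.einsum("t...,t...->...", a, a)
        syy = np.einsum("t...,t...->...", b, b)
        sxy = np.einsum("t...,t...->...", a, b)
    else:
        ok = np.isfinite(a) & np.isfinite(b)
        x = np.where(ok, a, 0.0)
        y = np.where(ok, b, 0.0)
        n = ok.sum(axis=0).astype(float)
        sx, sy = x.sum(axis=0), y.sum(axis=0)
        sxx, syy = (x * x).sum(axis=0), (y * y).sum(axis=0)
        sxy = (x * y).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
    r[(n < n_min)] = np.nan
    return np.clip(r, -1.0, 1.0)


def window_drive(windows, channel: int | None = None) -> np.ndarray:
    """Mean channel intensity over the non-NaN gaze window per time point;
    the default drive series for lag estimation. Returns T (single channel)
    or T x C."""
    data = windows.data if isinstance(windows, GazeWindowStack) else np.asarray(windows, float)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(data, axis=(1, 2))
    return mean if channel is None else mean[:, channel]
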