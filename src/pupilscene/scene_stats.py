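"""Scene-statistics transforms: per-channel gamma luminance, CIELAB
conversion, gaze-centered window extraction with off-screen NaNs, and block
downsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import FrameStack

#: channel spaces carried on GazeWindowStack
RGB_LUM = "rgb_lum"
CIELAB = "cielab"


@dataclass(frozen=True)
class ChannelGammaFit:
    """Result of fitting L = scale * (v/255)**gamma for one channel."""

    gamma: float
    scale: float
    resid_norm: float


@dataclass(frozen=True)
class GammaParams:
    """Per-channel display gamma exponents and peak-luminance scales.

    Unit scales are the default: Pearson correlation is invariant to
    positive rescaling, so cd/m^2 calibration only matters for reporting
    absolute luminances.
    """

    gamma_r: float = 2.24
    gamma_g: float = 2.23
    gamma_b: float = 2.22
    scale_r: float = 1.0
    scale_g: float = 1.0
    scale_b: float = 1.0

    def __post_init__(self) -> None:
        if min(self.gamma_r, self.gamma_g, self.gamma_b) <= 0:
            raise ValueError("gamma exponents must be positive")
        if min(self.scale_r, self.scale_g, self.scale_b) <= 0:
            raise ValueError("scales must be positive")

    @property
    def gammas(self) -> np.ndarray:
        return np.array([self.gamma_r, self.gamma_g, self.gamma_b])

    @property
    def scales(self) -> np.ndarray:
        return np.array([self.scale_r, self.scale_g, self.scale_b])


@dataclass
class GazeWindowStack:
    """Per-time-point gaze-centered channel windows.

    ``data`` is T x n x n x C with NaN marking off-screen cells (identical
    across channels at a given (t, row, col)). The gaze position sits at
    cell (n//2, n//2); row indices increase downward, so row < n//2 means
    above gaze.
    """

    data: np.ndarray
    channel_space: str = RGB_LUM
    px_per_cell: int = 10

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 4:
            raise ValueError("data must be T x n x n x C")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def center(self) -> int:
        return self.data.shape[1] // 2


def fit_gamma(levels, measured) -> ChannelGammaFit:
    """Least-squares fit of L = scale * (v/255)**gamma for one channel.

    ``levels`` are 8-bit codes (0-255), ``measured`` luminances in any
    positive unit. Requires at least 4 distinct levels including one at or
    above code 200 so the scale is identifiable.
    """
    levels = np.asarray(levels, float)
    measured = np.asarray(measured, float)
    if levels.shape != measured.shape:
        raise ValueError("levels and measured must have equal length")
    if len(np.unique(levels)) < 4:
        raise ValueError("need at least 4 distinct intensity levels")
    if levels.max() < 200:
        raise ValueError("need a high intensity level (>= 200) to anchor scale")
    if np.any(measured < 0):
        raise ValueError("measured luminance must be non-negative")
    if np.all(measured == 0):
        raise ValueError("all luminance measurements are zero")
    order = np.argsort(levels)
    if np.any(np.diff(measured[order]) < -0.05 * measured.max()):
        warnings.warn("luminance series is non-monotone beyond tolerance")

    def model(v, gamma, scale):
        return scale * (v / 255.0) ** gamma

    p0 = (2.2, float(measured.max()))
    popt, _ = curve_fit(model, levels, measured, p0=p0, maxfev=10000)
    resid = measured - model(levels, *popt)
    return ChannelGammaFit(gamma=float(popt[0]), scale=float(popt[1]),
                           resid_norm=float(np.linalg.norm(resid)))


def gamma_transform(frames, params: GammaParams = GammaParams()) -> np.ndarray:
    """Map 8-bit RGB frames to per-channel luminance, scale*(v/255)**gamma.

    Accepts a FrameStack or an array whose last axis is the 3 channels;
    returns float64 of the same shape.
    """
    arr = frames.frames if isinstance(frames, FrameStack) else np.asarray(frames)
    if arr.dtype == np.uint8:
        # exact 256-entry lookup per channel; much faster than elementwise pow
        codes = np.arange(256.0) / 255.0
        lut = params.scales * codes[:, None] ** params.gammas  # 256 x 3
        out = np.empty(arr.shape, float)
        for c in range(3):
            out[..., c] = lut[:, c][arr[..., c]]
        return out
    arr = arr.astype(float) / 255.0
    return params.scales * arr ** params.gammas


def gamma_lut(params: GammaParams = GammaParams()) -> np.ndarray:
    """256 x 3 lookup table of the per-channel gamma transform."""
    codes = np.arange(256.0) / 255.0
    return params.scales * codes[:, None] ** params.gammas


def gamma_transform_fn(params: GammaParams = GammaParams()):
    """Per-frame gamma transform closure carrying its lookup table.

    :func:`build_gaze_window_stack` recognises the attached ``lut`` and
    applies it to the extracted window only, which is much cheaper than
    transforming whole frames.
    """
    def fn(frame):
        return gamma_transform(frame, params)

    fn.lut = gamma_lut(params)
    return fn


def rgb_to_cielab(frames, paper_polarity: bool = False) -> np.ndarray:
    """Convert 8-bit RGB frames to CIELAB (sRGB primaries, D65 white).

    L* lies in [0, 100]; by CIE convention positive a* is red and negative
    b* is blue. ``paper_polarity=True`` flips the a* sign so that red is
    negative and green positive, matching reports that describe the a* axis
    that way round.
    """
    from skimage.color import rgb2lab

    arr = frames.frames if isinstance(frames, FrameStack) else np.asarray(frames)
    lab = rgb2lab(arr.astype(np.uint8))
    if paper_polarity:
        lab = lab.copy()
        lab[..., 1] = -lab[..., 1]
    return lab


def extract_gaze_window(frame: np.ndarray, gaze, half: int = 350) -> np.ndarray:
    """Cut a (2*half) x (2*half) x C window centered on the gaze pixel.

    The window covers rows gaze_y-half .. gaze_y+half-1 and the analogous
    columns, with gaze at index [half, half]; cells falling off-screen are
    NaN. A NaN or off-screen gaze yields an all-NaN window so the time axis
    stays aligned with the pupil series.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        frame = frame[..., None]
    H, W, C = frame.shape
    size = 2 * half
    out = np.full((size, size, C), np.nan)
    x, y = gaze
    if not (np.isfinite(x) and np.isfinite(y)):
        return out
    x, y = int(round(x)), int(round(y))
    if not (0 <= x < W and 0 <= y < H):
        return out
    r0, r1 = y - half, y + half
    c0, c1 = x - half, x + half
    sr0, sr1 = max(r0, 0), min(r1, H)
    sc0, sc1 = max(c0, 0), min(c1, W)
    out[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = frame[sr0:sr1, sc0:sc1]
    return out


def block_downsample(window: np.ndarray, factor: int = 10) -> np.ndarray:
    """Average non-overlapping factor x factor blocks, ignoring NaNs.

    A block with no finite values stays NaN. ``factor`` must divide both
    spatial dimensions.
    """
    window = np.asarray(window, float)
    squeeze = window.ndim == 2
    if squeeze:
        window = window[..., None]
    h, w, c = window.shape
    if h % factor or w % factor:
        raise ValueError(f"factor {factor} does not divide window shape {(h, w)}")
    blocks = window.reshape(h // factor, factor, w // factor, factor, c)
    nan = np.isnan(blocks)
    if not nan.any():
        out = blocks.mean(axis=(1, 3))
    else:
        s = np.where(nan, 0.0, blocks).sum(axis=(1, 3))
        cnt = (~nan).sum(axis=(1, 3))
        with np.errstate(invalid="ignore"):
            out = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    return out[..., 0] if squeeze else out


def build_gaze_window_stack(frames, gaze_xy, half: int = 350,
                            factor: int = 10,
                            channel_space: str = RGB_LUM,
                            frame_transform=None) -> GazeWindowStack:
    """Extract and block-downsample a gaze window for every frame.

    ``frames`` is a T x H x W x C array (a FrameStack is accepted);
    ``gaze_xy`` is T x 2 in screen pixels. When ``frame_transform`` is
    given, it is applied to each frame before extraction (e.g. the gamma
    luminance transform or a CIELAB conversion), which keeps memory bounded
    for long recordings.
    """
    if isinstance(frames, FrameStack):
        frames = frames.frames
    frames = np.asarray(frames)
    gaze_xy = np.asarray(gaze_xy, float)
    if len(frames) != len(gaze_xy):
        raise ValueError("frames and gaze trajectories differ in length")
    n = 2 * half // factor
    T, C = len(frames), frames.shape[-1]
    data = np.empty((T, n, n, C))
    lut = getattr(frame_transform, "lut", None)
    fast = lut is not None and frames.dtype == np.uint8
    H, W = frames.shape[1:3]
    buf = np.empty((2 * half, 2 * half, C)) if fast else None
    for t in range(T):
        if fast:
            x, y = gaze_xy[t]
            interior = (np.isfinite(x) and np.isfinite(y)
                        and half <= round(x) <= W - half
                        and half <= round(y) <= H - half)
            if interior:
                # fully on-screen: no NaN canvas, plain block means
                xi, yi = int(round(x)), int(round(y))
                region = frames[t, yi - half:yi + half, xi - half:xi + half]
                for c in range(C):
                    buf[..., c] = lut[:, c][region[..., c]]
                rows = buf.reshape(n, factor, 2 * half, C).sum(axis=1)
                data[t] = rows.reshape(n, n, factor, C).sum(axis=2) / factor**2
                continue
            win = _extract_window_lut(frames[t], gaze_xy[t], half, lut)
        else:
            frame = frames[t] if frame_transform is None else frame_transform(frames[t])
            win = extract_gaze_window(frame, gaze_xy[t], half)
        data[t] = block_downsample(win, factor)
    return GazeWindowStack(data=data, channel_space=channel_space,
                           px_per_cell=factor)


def _extract_window_lut(frame: np.ndarray, gaze, half: int,
                        lut: np.ndarray) -> np.ndarray:
    """Extract a gaze window from an 8-bit frame, applying a 256 x C lookup
    table to the on-screen region only. Mirrors extract_gaze_window."""
    H, W, C = frame.shape
    size = 2 * half
    out = np.full((size, size, C), np.nan)
    x, y = gaze
    if not (np.isfinite(x) and np.isfinite(y)):
        return out
    x, y = int(round(x)), int(round(y))
    if not (0 <= x < W and 0 <= y < H):
        return out
    r0, c0 = y - half, x - half
    sr0, sr1 = max(r0, 0), min(y + half, H)
    sc0, sc1 = max(c0, 0), min(x + half, W)
    region = frame[sr0:sr1, sc0:sc1]
    dest = out[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0]
    for c in range(C):
        dest[..., c] = lut[:, c][region[..., c]]
    return out


def nan_fraction_map(stack: GazeWindowStack) -> np.ndarray:
    """Per-cell fraction of time points that are NaN (off-screen)."""
    if len(stack) < 1:
        raise ValueError("empty stack")
    return np.isnan(stack.data[..., 0]).mean(axis=0)
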