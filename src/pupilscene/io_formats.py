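"""Readers and writers for the tabular, image and map formats the pipeline touches.

Eye-tracking exports are plain CSV/TSV tables whose column names vary by
vendor, so the reader takes an explicit column map. Scene frames come from a
directory of PNG snapshots (or an MP4, if an ffmpeg-capable imageio backend
is present). Result maps are written as plain-text CSV matrices with a JSON
sidecar describing what each matrix is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


# ---------------------------------------------------------------------------
# Eye-tracking tables
# ---------------------------------------------------------------------------

#: canonical column names expected by the pipeline
EYETRACK_COLUMNS = (
    "time",
    "pupil_left",
    "pupil_right",
    "gaze_x",
    "gaze_y",
)


@dataclass
class EyeTrackTable:
    """A raw binocular eye-tracking export.

    ``time`` is in seconds and must be monotone non-decreasing. Pupil sizes
    are kept in device units (millimetres or arbitrary units); missing
    samples are NaN with the corresponding validity flag set to False.
    """

    time: np.ndarray
    pupil_left: np.ndarray
    pupil_right: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    validity_left: np.ndarray
    validity_right: np.ndarray
    fs: float
    units: str = "a.u."

    def __post_init__(self) -> None:
        n = len(self.time)
        for f in ("pupil_left", "pupil_right", "gaze_x", "gaze_y",
                  "validity_left", "validity_right"):
            if len(getattr(self, f)) != n:
                raise FormatError(f"column {f!r} length differs from time")
        if self.fs <= 0:
            raise FormatError("sampling rate must be positive")
        if np.any(np.diff(self.time) < 0):
            raise FormatError("time must be monotone non-decreasing")

    def __len__(self) -> int:
        return len(self.time)


def read_eyetrack(path, column_map: dict | None = None,
                  units: str = "a.u.") -> EyeTrackTable:
    """Read a delimited eye-tracking export.

    Parameters
    ----------
    path:
        CSV or TSV file; the delimiter is sniffed.
    column_map:
        Mapping from canonical names (``time``, ``pupil_left``,
        ``pupil_right``, ``gaze_x``, ``gaze_y`` and optionally
        ``validity_left``/``validity_right``) to the column names used in
        the file. Identity by default.

    Missing or blank cells become NaN with validity False; the sampling rate
    is inferred from the median timestamp spacing. The output has exactly as
    many rows as the input.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    column_map = dict(column_map or {})
    for canon in EYETRACK_COLUMNS:
        name = column_map.get(canon, canon)
        if name not in df.columns:
            raise FormatError(f"required column {name!r} (for {canon!r}) "
                              f"missing from {path.name}")

    def col(canon, default=None):
        name = column_map.get(canon, canon)
        if name not in df.columns:
            return default
        return pd.to_numeric(df[name], errors="coerce").to_numpy(float)

    time = col("time")
    if np.any(~np.isfinite(time)):
        raise FormatError("time column contains missing values")
    if np.any(np.diff(time) < 0):
        raise FormatError("time column is not monotone non-decreasing")
    dt = np.median(np.diff(time)) if len(time) > 1 else np.nan
    if not np.isfinite(dt) or dt <= 0:
        raise FormatError("cannot infer sampling rate from timestamps")

    pl, pr = col("pupil_left"), col("pupil_right")
    vl = col("validity_left")
    vr = col("validity_right")
    validity_left = np.isfinite(pl) if vl is None else (vl > 0) & np.isfinite(pl)
    validity_right = np.isfinite(pr) if vr is None else (vr > 0) & np.isfinite(pr)
    pl = np.where(validity_left, pl, np.nan)
    pr = np.where(validity_right, pr, np.nan)

    return EyeTrackTable(
        time=time, pupil_left=pl, pupil_right=pr,
        gaze_x=col("gaze_x"), gaze_y=col("gaze_y"),
        validity_left=validity_left, validity_right=validity_right,
        fs=1.0 / dt, units=units,
    )


# ---------------------------------------------------------------------------
# Frame stacks
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """A stack of 8-bit RGB screen frames with timestamps in seconds."""

    frames: np.ndarray       # T x H x W x 3 uint8
    timestamps: np.ndarray   # seconds, strictly increasing
    fs: float = 12.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise FormatError("frames must be T x H x W x 3")
        if self.frames.shape[1] == 0 or self.frames.shape[2] == 0:
            raise FormatError("frames must have positive height and width")
        self.timestamps = np.asarray(self.timestamps, float)
        if len(self.timestamps) != len(self.frames):
            raise FormatError("timestamps length must match frame count")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise FormatError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self):
        return self.frames.shape


def read_frames(path, stride: int = 1, fs: float = 12.0) -> FrameStack:
    """Read frames from a PNG directory (sorted by name) or an MP4 file.

    ``stride`` keeps every ``stride``-th frame starting at index 0, so the
    kept indices are 0, stride, 2*stride, ...; ``fs`` is the rate of the
    *source* sequence and the output stack is at ``fs / stride``.
    """
    import imageio.v3 as iio

    if stride < 1:
        raise ValueError("stride must be >= 1")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")

    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".bmp", ".jpg", ".jpeg"})
        if not files:
            raise FormatError(f"no image files in {path}")
        imgs = []
        shape = None
        for i, f in enumerate(files):
            if i % stride:
                continue
            img = iio.imread(f)
            if img.ndim == 2:
                img = np.repeat(img[..., None], 3, axis=-1)
            img = img[..., :3]
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise FormatError(
                    f"mixed frame sizes: {f.name} is {img.shape[:2]}, "
                    f"expected {shape[:2]}")
            imgs.append(img.astype(np.uint8))
        frames = np.stack(imgs)
    else:
        try:
            raw = iio.imread(path, plugin="pyav")
        except Exception as exc:  # pragma: no cover - backend dependent
            raise FormatError(
                f"cannot decode video {path.name}: {exc}; install an "
                "ffmpeg-capable imageio backend or supply a PNG directory"
            ) from exc
        frames = np.asarray(raw)[::stride, ..., :3].astype(np.uint8)
        if frames.size == 0:
            raise FormatError(f"empty video: {path}")

    out_fs = fs / stride
    ts = np.arange(len(frames)) / out_fs
    return FrameStack(frames=frames, timestamps=ts, fs=out_fs)


# ---------------------------------------------------------------------------
# Map bundles
# ---------------------------------------------------------------------------

def write_map_bundle(maps, path, metadata: dict | None = None) -> list:
    """Write 2-D result maps as CSV matrices with a JSON sidecar each.

    ``maps`` is either a single 2-D array (stored under the name "map") or a
    mapping of name -> 2-D array. Values are stored with 17 significant
    digits so a round trip is exact at double precision.
    """
    if isinstance(maps, np.ndarray):
        maps = {"map": maps}
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in maps.items():
        arr = np.asarray(arr, float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError(f"map {name!r} must be a non-empty 2-D array")
        csv_path = path / f"{name}.csv"
        np.savetxt(csv_path, arr, fmt="%.17g", delimiter=",")
        meta = dict(metadata or {})
        meta.update({"name": name, "shape": list(arr.shape)})
        json_path = path / f"{name}.json"
        json_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
        written.extend([csv_path, json_path])
    return written


def read_map_bundle(path) -> dict:
    """Read back a directory written by :func:`write_map_bundle`.

    Returns ``{name: (array, metadata)}``.
    """
    path = Path(path)
    out = {}
    for csv_path in sorted(path.glob("*.csv")):
        meta_path = csv_path.with_suffix(".json")
        if not meta_path.exists():
            continue  # not a map matrix (e.g. a plain results table)
        arr = np.loadtxt(csv_path, delimiter=",", ndmin=2)
        out[csv_path.stem] = (arr, json.loads(meta_path.read_text()))
    return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated analysis configuration, loadable from JSON.

    Unknown keys are rejected so that typos fail loudly instead of silently
    falling back to defaults.
    """

    lag_ms: float = 500.0
    window_half: int = 350
    downsample_factor: int = 10
    fdr_q: float = 0.01
    channel_space: str = "rgb_lum"     # "rgb_lum" | "cielab"
    n_min: int | None = None           # min paired samples per map cell
    target_fs: float = 12.0
    max_lag_ms: float = 2000.0
    seed: int = 0
    gamma: tuple = (2.24, 2.23, 2.22)  # red, green, blue exponents
    exp2_fdr_q: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.lag_ms <= self.max_lag_ms:
            raise ValueError("lag_ms must lie in [0, max_lag_ms]")
        if self.window_half <= 0 or self.downsample_factor <= 0:
            raise ValueError("window geometry must be positive")
        if (2 * self.window_half) % self.downsample_factor:
            raise ValueError("downsample factor must divide the window size")
        if not 0 < self.fdr_q < 1 or not 0 < self.exp2_fdr_q < 1:
            raise ValueError("FDR levels must lie in (0, 1)")
        if self.channel_space not in ("rgb_lum", "cielab"):
            raise ValueError("channel_space must be 'rgb_lum' or 'cielab'")
        if self.target_fs <= 0:
            raise ValueError("target_fs must be positive")
        if any(g <= 0 for g in self.gamma):
            raise ValueError("gamma exponents must be positive")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "gamma" in data:
            data = dict(data)
            data["gamma"] = tuple(data["gamma"])
        return cls(**data)

    def to_json(self, path) -> None:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["gamma"] = list(d["gamma"])
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))
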