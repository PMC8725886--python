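"""Pupil-trace cleaning: eye selection, velocity outlier removal, blink
detection and repair, and downsampling to the analysis rate.

The cleaning chain is:

1. pick the eye with the least missing data,
2. two-pass velocity-based despiking (2 SD then 2.5 SD) with linear
   interpolation of flagged samples,
3. classify contiguous missing runs of 50-500 ms as blinks (longer runs are
   dropouts and stay missing),
4. repair each blink by padding its edges (velocity criterion on a smoothed
   copy, up to 50 ms each side) and interpolating linearly across the padded
   interval,
5. bin-average down to the frame rate of the paired scene recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np


@dataclass
class PupilTrace:
    """A regularly sampled pupil-size series.

    ``value`` is NaN exactly where ``valid`` is False. ``time`` is in
    seconds on a regular 1/fs grid.
    """

    time: np.ndarray
    value: np.ndarray
    valid: np.ndarray
    fs: float
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.value = np.asarray(self.value, float)
        if self.valid is None:
            self.valid = np.isfinite(self.value)
        self.valid = np.asarray(self.valid, bool)
        if not (len(self.time) == len(self.value) == len(self.valid)):
            raise ValueError("time, value and valid must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        # enforce value NaN <=> valid False
        self.valid = self.valid & np.isfinite(self.value)
        self.value = np.where(self.valid, self.value, np.nan)

    def __len__(self) -> int:
        return len(self.value)

    @classmethod
    def from_values(cls, value, fs, t0: float = 0.0, units: str = "a.u."):
        value = np.asarray(value, float)
        time = t0 + np.arange(len(value)) / fs
        return cls(time=time, value=value, valid=np.isfinite(value), fs=fs,
                   units=units)


@dataclass(frozen=True)
class BlinkInterval:
    """A half-open run [onset, offset) of missing samples classified as a blink."""

    onset: int
    offset: int
    duration_ms: float

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")


@dataclass(frozen=True)
class PreprocessParams:
    k1: float = 2.0            # first-pass velocity SD multiplier
    k2: float = 2.5            # second-pass velocity SD multiplier
    blink_min_ms: float = 50.0
    blink_max_ms: float = 500.0
    blink_pad_ms: float = 50.0
    hann_width_ms: float = 11.0
    edge_mad_mult: float = 3.0  # blink-edge velocity threshold, in MADs
    target_fs: float = 12.0

    def __post_init__(self) -> None:
        if not 0 < self.k1 < self.k2:
            raise ValueError("need 0 < k1 < k2")
        for name in ("blink_min_ms", "blink_max_ms", "blink_pad_ms",
                     "hann_width_ms", "target_fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------


def select_eye(left: PupilTrace, right: PupilTrace) -> PupilTrace:
    """Return the trace with the smaller fraction of invalid samples.

    Ties go to the left eye. Raises if both eyes are entirely missing.
    """
    if len(left) != len(right):
        raise ValueError("left and right traces differ in length")
    if left.fs != right.fs:
        raise ValueError("left and right traces differ in sampling rate")
    fl = missing_fraction(left)
    fr = missing_fraction(right)
    if fl == 1.0 and fr == 1.0:
        raise ValueError("both eyes are entirely missing")
    return left if fl <= fr else right


def missing_fraction(trace: PupilTrace) -> float:
    """Fraction of samples marked invalid."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    return float(np.mean(~trace.valid))


def _velocity(value: np.ndarray, fs: float) -> np.ndarray:
    """First difference scaled to units/s; v[i] describes sample i (later one)."""
    v = np.full(len(value), np.nan)
    v[1:] = np.diff(value) * fs
    return v


def _interp_at(value: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Linearly interpolate value at boolean-indexed positions from the
    nearest finite neighbours (constant extrapolation at the ends)."""
    out = value.copy()
    finite = np.isfinite(value) & ~idx
    if not finite.any():
        return out
    pos = np.flatnonzero(finite)
    out[idx] = np.interp(np.flatnonzero(idx), pos, value[pos])
    return out


def remove_velocity_outliers(trace: PupilTrace,
                             params: PreprocessParams = PreprocessParams()
                             ) -> PupilTrace:
    """Two-pass velocity-based despiking.

    Pass 1 flags samples whose velocity deviates from the mean by more than
    ``k1`` SDs; pass 2 recomputes mean/SD on the surviving velocities and
    flags deviations beyond ``k2`` SDs. Flagged samples are replaced by
    linear interpolation between their nearest surviving neighbours.
    """
    if int(np.sum(trace.valid)) < 3:
        raise ValueError("need at least 3 valid samples")
    v = _velocity(trace.value, trace.fs)
    finite = np.isfinite(v)
    if not finite.any() or np.nanstd(v[finite]) == 0:
        warnings.warn("zero velocity variance; trace returned unchanged")
        return trace

    mu, sd = np.mean(v[finite]), np.std(v[finite])
    flag1 = finite & (np.abs(v - mu) > params.k1 * sd)

    keep = finite & ~flag1
    if keep.any() and np.std(v[keep]) > 0:
        mu2, sd2 = np.mean(v[keep]), np.std(v[keep])
        flag2 = keep & (np.abs(v - mu2) > params.k2 * sd2)
    else:
        flag2 = np.zeros_like(flag1)

    flagged = flag1 | flag2
    if not flagged.any():
        return trace
    value = trace.value.copy()
    value[flagged] = np.nan
    value = _interp_at(value, flagged)
    valid = trace.valid | flagged  # repaired samples are usable again
    valid &= np.isfinite(value)
    return replace(trace, value=np.where(valid, value, np.nan), valid=valid)


def detect_blinks(trace: PupilTrace,
                  params: PreprocessParams = PreprocessParams()
                  ) -> list[BlinkInterval]:
    """Maximal runs of contiguous invalid samples whose duration lies within
    the blink bounds; longer runs are dropouts and are not returned."""
    invalid = ~trace.valid
    blinks: list[BlinkInterval] = []
    n = len(invalid)
    i = 0
    while i < n:
        if invalid[i]:
            j = i
            while j < n and invalid[j]:
                j += 1
            dur_ms = (j - i) / trace.fs * 1000.0
            if params.blink_min_ms <= dur_ms <= params.blink_max_ms:
                blinks.append(BlinkInterval(i, j, dur_ms))
            i = j
        else:
            i += 1
    return blinks


def _hann_smooth(value: np.ndarray, fs: float, width_ms: float) -> np.ndarray:
    n = int(round(width_ms * fs / 1000.0))
    n = max(3, n + 1 if n % 2 == 0 else n)  # nearest odd count, at least 3
    win = np.hanning(n + 2)[1:-1]  # strictly positive taps
    win /= win.sum()
    pad = n // 2
    padded = np.pad(value, pad, mode="edge")
    return np.convolve(padded, win, mode="valid")


def repair_blinks(trace: PupilTrace, blinks: list[BlinkInterval],
                  params: PreprocessParams = PreprocessParams()
                  ) -> PupilTrace:
    """Interpolate each blink after extending its edges.

    A smoothed copy of the trace (Hanning window of ~``hann_width_ms``)
    provides a velocity estimate; the onset is walked backward and the
    offset forward, each up to ``blink_pad_ms``, until the smoothed
    |velocity| falls below ``edge_mad_mult`` MADs of its whole-trace
    distribution. The padded interval is then linearly interpolated between
    its boundary samples; a blink touching the trace boundary is filled with
    the nearest valid value.
    """
    if not blinks:
        return trace
    n = len(trace)
    filled = _interp_at(trace.value, ~trace.valid)
    if not np.isfinite(filled).all():
        raise ValueError("trace has no valid samples to interpolate from")
    smoothed = _hann_smooth(filled, trace.fs, params.hann_width_ms)
    sv = np.abs(_velocity(smoothed, trace.fs))
    sv[0] = sv[1] if n > 1 else 0.0
    med = np.nanmedian(sv)
    thresh = params.edge_mad_mult * np.nanmedian(np.abs(sv - med))
    pad = max(1, int(round(params.blink_pad_ms * trace.fs / 1000.0)))

    value = trace.value.copy()
    valid = trace.valid.copy()
    for blink in blinks:
        on, off = blink.onset, blink.offset
        # walk onset backward while the smoothed velocity is still large
        lo = max(0, on - pad)
        while on > lo and sv[on - 1] >= thresh:
            on -= 1
        hi = min(n, off + pad)
        while off < hi and off < n and sv[off] >= thresh:
            off += 1
        left = on - 1
        right = off
        if left < 0 and right >= n:
            continue  # nothing to anchor on; leave missing
        if left < 0:
            value[:right] = value[right]
            valid[:right] = valid[right]
        elif right >= n:
            value[left + 1:] = value[left]
            valid[left + 1:] = valid[left]
        else:
            span = np.arange(left, right + 1)
            value[span] = np.interp(span, [left, right],
                                    [value[left], value[right]])
            valid[on:off] = True
    valid &= np.isfinite(value)
    return replace(trace, value=np.where(valid, value, np.nan), valid=valid)


def downsample_trace(trace: PupilTrace, target_fs: float,
                     t0: float | None = None) -> PupilTrace:
    """Bin-average to ``target_fs``: output sample k is the mean of the valid
    input samples whose time falls in [t0 + k/target_fs, t0 + (k+1)/target_fs);
    an all-invalid bin is NaN."""
    if target_fs >= trace.fs:
        raise ValueError("target_fs must be below the trace sampling rate")
    if t0 is None:
        t0 = float(trace.time[0]) if len(trace) else 0.0
    rel = trace.time - t0
    n_out = int(np.floor(rel[-1] * target_fs + 1e-9)) + 1 if len(trace) else 0
    bins = np.floor(rel * target_fs + 1e-9).astype(int)
    ok = (bins >= 0) & (bins < n_out) & trace.valid
    sums = np.bincount(bins[ok], weights=trace.value[ok], minlength=n_out)
    counts = np.bincount(bins[ok], minlength=n_out)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    time = t0 + np.arange(n_out) / target_fs
    return PupilTrace(time=time, value=out, valid=counts > 0, fs=target_fs,
                      units=trace.units)


def preprocess_trace(left: PupilTrace, right: PupilTrace,
                     params: PreprocessParams = PreprocessParams()
                     ) -> PupilTrace:
    """Full cleaning chain: eye selection, despiking, blink repair, and
    downsampling to ``params.target_fs``. Dropouts (missing runs longer than
    the blink upper bound) remain NaN."""
    trace = select_eye(left, right)
    # blinks first, while their partial-closure edges are still intact: the
    # despiking pass would otherwise interpolate across the closure ramps and
    # flatten the edge velocities that the blink-padding criterion relies on
    blinks = detect_blinks(trace, params)
    trace = repair_blinks(trace, blinks, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trace = remove_velocity_outliers(trace, params)
    return downsample_trace(trace, params.target_fs)
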