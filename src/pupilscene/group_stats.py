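"""Group-level inference on correlation maps.

Fisher Z transform, pixel-wise one-sample t maps with Benjamini-Hochberg
FDR control, dependent-correlation comparisons between channels (Williams t
by default, Steiger z as an alternative), and the per-subject
above-vs-below-gaze summary test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class GroupMapResult:
    mean_z: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: np.ndarray
    q: float | None = None
    q_mask: np.ndarray | None = None
    p_adjusted: np.ndarray | None = None


@dataclass
class DependentComparison:
    """Group comparison of two overlapping dependent correlations."""

    stat: np.ndarray          # subjects x ... per-subject Williams t (or Steiger z)
    group_t: np.ndarray
    group_p: np.ndarray
    df: np.ndarray
    q: float
    q_mask: np.ndarray
    method: str


def fisher_z(r):
    """z = atanh(r), with |r| clipped to 1 - 1e-7 first.

    Accepts scalars or arrays; NaN passes through. |r| > 1 is an error.
    """
    r = np.asarray(r, float)
    finite = np.isfinite(r)
    if np.any(np.abs(r[finite]) > 1):
        raise ValueError("|r| must not exceed 1")
    clipped = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    out = np.arctanh(clipped)
    if out.ndim == 0:
        return float(out)
    return out


def one_sample_t_map(z_stack: np.ndarray, n_subj_min: int = 3) -> GroupMapResult:
    """Pixel-wise one-sample t test of the subject stack against 0.

    ``z_stack`` is subjects x (map shape). Cells with fewer than
    ``n_subj_min`` finite subject values are NaN; zero between-subject
    variance yields p = NaN with a warning. Two-sided p values.
    """
    z = np.asarray(z_stack, float)
    if z.ndim < 2:
        raise ValueError("z_stack must be subjects x map")
    finite = np.isfinite(z)
    m = finite.sum(axis=0).astype(float)
    enough = m >= n_subj_min
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(m > 0, np.nansum(np.where(finite, z, 0.0), axis=0)
                        / np.maximum(m, 1), np.nan)
        dev = np.where(finite, z - mean, 0.0)
        sd = np.sqrt(np.where(m > 1, (dev ** 2).sum(axis=0)
                              / np.maximum(m - 1, 1), np.nan))
        t = mean / (sd / np.sqrt(m))
    df = m - 1
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(df, 1))
    zero_var = enough & (sd == 0)
    if np.any(zero_var):
        warnings.warn("zero between-subject variance at some cells; p set NaN")
        p = np.where(zero_var, np.nan, p)
        t = np.where(zero_var, np.nan, t)
    t = np.where(enough, t, np.nan)
    p = np.where(enough, p, np.nan)
    mean = np.where(enough, mean, np.nan)
    return GroupMapResult(mean_z=mean, t=t, p=p, df=df)


def bh_fdr(p, q: float = 0.01):
    """Benjamini-Hochberg step-up over the finite entries of ``p``.

    Returns ``(mask, p_adjusted)`` with the same shape as the input; NaN
    entries are excluded and stay NaN in the adjusted values (False in the
    mask).
    """
    p = np.asarray(p, float)
    shape = p.shape
    flat = p.ravel()
    finite = np.isfinite(flat)
    mask = np.zeros(flat.shape, bool)
    adj = np.full(flat.shape, np.nan)
    m = int(finite.sum())
    if m == 0:
        return mask.reshape(shape), adj.reshape(shape)
    pv = flat[finite]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p values must lie in [0, 1]")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order]
    thresh = q * np.arange(1, m + 1) / m
    passed = ranked <= thresh
    k_star = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    rej = np.zeros(m, bool)
    rej[order[:k_star]] = True
    # adjusted p: cumulative minimum from the largest rank down
    raw_adj = ranked * m / np.arange(1, m + 1)
    raw_adj = np.minimum.accumulate(raw_adj[::-1])[::-1]
    adj_sorted = np.minimum(raw_adj, 1.0)
    adj_vals = np.empty(m)
    adj_vals[order] = adj_sorted
    mask[finite] = rej
    adj[finite] = adj_vals
    return mask.reshape(shape), adj.reshape(shape)


def group_map(z_stack: np.ndarray, q: float = 0.01,
              n_subj_min: int = 3) -> GroupMapResult:
    """One-sample t map plus BH-FDR thresholding at level ``q``."""
    res = one_sample_t_map(z_stack, n_subj_min=n_subj_min)
    mask, adj = bh_fdr(res.p, q)
    res.q = q
    res.q_mask = mask
    res.p_adjusted = adj
    return res


def williams_t(r12, r13, r23, n):
    """Hotelling-Williams t for two dependent overlapping correlations.

    Tests r12 = r13 where variables 2 and 3 are both correlated with the
    shared variable 1 and with each other (r23). Returns ``(t, df)`` with
    df = n - 3; the sign of t matches the sign of r12 - r13. Vectorized
    over arrays.
    """
    r12 = np.asarray(r12, float)
    r13 = np.asarray(r13, float)
    r23 = np.asarray(r23, float)
    n = np.asarray(n, float)
    if np.any(n <= 3):
        raise ValueError("need n > 3")
    for r in (r12, r13, r23):
        if np.any(np.abs(r[np.isfinite(r)]) > 1):
            raise ValueError("correlations must lie in [-1, 1]")
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    finite = np.isfinite(det)
    if np.any(det[finite] < -1e-9):
        raise ValueError("incoherent correlation triplet (negative determinant)")
    det = np.clip(det, 0.0, None)
    rbar = (r12 + r13) / 2.0
    denom = 2 * ((n - 1) / (n - 3)) * det + rbar**2 * (1 - r23)**3
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (r12 - r13) * np.sqrt((n - 1) * (1 + r23) / denom)
    df = n - 3
    if t.ndim == 0:
        return float(t), float(df)
    return t, df


def steiger_z(r12, r13, r23, n):
    """Steiger's Z for two dependent overlapping correlations.

    Fisher-z difference divided by its null standard error using the pooled
    correlation; returns ``(z, None)`` (the reference distribution is
    standard normal). Vectorized.
    """
    r12 = np.asarray(r12, float)
    r13 = np.asarray(r13, float)
    r23 = np.asarray(r23, float)
    n = np.asarray(n, float)
    if np.any(n <= 3):
        raise ValueError("need n > 3")
    z12 = fisher_z(r12)
    z13 = fisher_z(r13)
    rbar2 = ((r12 + r13) / 2.0) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (r23 * (1 - 2 * rbar2) - 0.5 * rbar2 * (1 - 2 * rbar2 - r23**2)) \
            / (1 - rbar2) ** 2
        z = (z12 - z13) * np.sqrt((n - 3) / (2 - 2 * cov))
    if np.ndim(z) == 0:
        return float(z), None
    return z, None


def dependent_comparison_map(maps_a: np.ndarray, maps_b: np.ndarray,
                             r23_maps: np.ndarray, n_time,
                             q: float = 0.01,
                             method: str = "williams") -> DependentComparison:
    """Compare two channels' correlation maps against the shared pupil series.

    ``maps_a``/``maps_b`` are subjects x map per-subject pupil-channel r
    maps; ``r23_maps`` the per-subject between-channel r maps; ``n_time``
    the per-subject paired sample count (scalar or per-subject vector).
    Per subject and cell a Williams t (or Steiger z) is computed, then the
    subject stack is tested against 0 with a one-sample t map and BH-FDR at
    level ``q``.
    """
    maps_a = np.asarray(maps_a, float)
    maps_b = np.asarray(maps_b, float)
    r23 = np.asarray(r23_maps, float)
    if maps_a.shape != maps_b.shape or maps_a.shape != r23.shape:
        raise ValueError("per-subject map stacks must share one shape")
    n_subj = maps_a.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects for a group comparison")
    n_time = np.asarray(n_time, float)
    if n_time.ndim == 0:
        n_time = np.full(n_subj, float(n_time))
    n_bc = n_time.reshape((n_subj,) + (1,) * (maps_a.ndim - 1))
    if method == "williams":
        stat, _ = williams_t(maps_a, maps_b, r23, n_bc)
    elif method == "steiger":
        stat, _ = steiger_z(maps_a, maps_b, r23, n_bc)
    else:
        raise ValueError("method must be 'williams' or 'steiger'")
    res = group_map(stat, q=q)
    return DependentComparison(stat=stat, group_t=res.t, group_p=res.p,
                               df=res.df, q=q, q_mask=res.q_mask,
                               method=method)


def upper_lower_test(r_map: np.ndarray, min_cells: int = 10):
    """Two-sample t between the correlations above and below the gaze row.

    ``r_map`` is a single-channel 2-D map; rows below the middle index are
    "upper visual field" (row index increases downward). The middle row is
    excluded. Negative t means the upper cells are more negative.
    """
    r_map = np.asarray(r_map, float)
    if r_map.ndim != 2:
        raise ValueError("r_map must be 2-D")
    mid = r_map.shape[0] // 2
    upper = r_map[:mid].ravel()
    lower = r_map[mid + 1:].ravel()
    upper = upper[np.isfinite(upper)]
    lower = lower[np.isfinite(lower)]
    if len(upper) < min_cells or len(lower) < min_cells:
        raise ValueError(f"need at least {min_cells} finite cells per half")
    t, p = stats.ttest_ind(upper, lower)
    return float(t), float(p)
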