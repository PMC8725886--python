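"""Controlled pupillary-light-response analysis.

Trial epochs (3 colors x 4 screen locations) are normalized to percent
signal change against a 500 ms pre-stimulus baseline, blink-contaminated
trials are dropped, subjects are kept only when every condition retains a
valid trial and at least half of all trials survive, the peak constriction
(PLRmin, the minimum of the condition-mean waveform in 0-2 s) is extracted,
and the subject x color x location table feeds a two-factor
repeated-measures ANOVA with Greenhouse-Geisser correction plus
FDR-corrected one-sample tests on the six planned difference scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .group_stats import bh_fdr

COLORS = ("red", "green", "blue")
LOCATIONS = ("top", "bottom", "left", "right")

#: epoch window (ms) and sampling rate of the canonical design
EPOCH_PRE_MS = 500
EPOCH_POST_MS = 2500
EPOCH_FS = 1000.0
PLR_WINDOW_MS = (0, 2000)       # inclusive search window for PLRmin
BLINK_QC_WINDOW_MS = (0, 1500)  # (0, 1500]: missing data here voids the trial


def epoch_time_ms(pre_ms: float = EPOCH_PRE_MS, post_ms: float = EPOCH_POST_MS,
                  fs: float = EPOCH_FS) -> np.ndarray:
    """Time axis in ms for an epoch spanning [-pre, post) at ``fs``."""
    step = 1000.0 / fs
    return np.arange(-pre_ms, post_ms, step)


@dataclass
class TrialEpoch:
    """A single stimulus-locked pupil epoch in device units."""

    color: str
    location: str
    samples: np.ndarray
    t_ms: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        self.t_ms = np.asarray(self.t_ms, float)
        if self.samples.shape != self.t_ms.shape:
            raise ValueError("samples and t_ms must align")
        if self.t_ms[0] > -EPOCH_PRE_MS or self.t_ms[-1] < PLR_WINDOW_MS[1]:
            raise ValueError("epoch must cover at least [-500, 2000] ms")


@dataclass
class Exp2Subject:
    """All trials of one subject as a matrix plus per-trial labels."""

    subject: str
    samples: np.ndarray       # trials x time, device units, NaN = missing
    t_ms: np.ndarray
    colors: np.ndarray        # per-trial color label
    locations: np.ndarray

    def trials(self):
        for i in range(len(self.samples)):
            yield TrialEpoch(color=self.colors[i], location=self.locations[i],
                             samples=self.samples[i], t_ms=self.t_ms)


# ---------------------------------------------------------------------------
# Normalization and QC
# ---------------------------------------------------------------------------

def percent_signal_change(samples: np.ndarray, t_ms: np.ndarray):
    """Normalize epochs to percent signal change against the pre-stimulus
    baseline.

    Baseline B is the mean of valid samples in [-500, 0) ms; the output is
    100 * (x - B) / B. A trial with under 50% valid baseline samples or a
    non-positive baseline is marked invalid (all-NaN row).

    Returns ``(normalized, ok)`` where ``ok`` flags trials with a usable
    baseline. ``samples`` may be one epoch (1-D) or trials x time.
    """
    samples = np.asarray(samples, float)
    one = samples.ndim == 1
    if one:
        samples = samples[None, :]
    t_ms = np.asarray(t_ms, float)
    base_win = (t_ms >= -EPOCH_PRE_MS) & (t_ms < 0)
    base = samples[:, base_win]
    n_base = base.shape[1]
    finite = np.isfinite(base)
    enough = finite.sum(axis=1) >= 0.5 * n_base
    with np.errstate(invalid="ignore"):
        b = np.nansum(np.where(finite, base, 0.0), axis=1) / np.maximum(
            finite.sum(axis=1), 1)
    ok = enough & (b > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = 100.0 * (samples - b[:, None]) / b[:, None]
    norm[~ok] = np.nan
    if one:
        return norm[0], bool(ok[0])
    return norm, ok


def trial_validity(samples: np.ndarray, t_ms: np.ndarray) -> np.ndarray:
    """True for trials with no missing sample in (0, 1500] ms post-onset."""
    samples = np.asarray(samples, float)
    if samples.ndim == 1:
        samples = samples[None, :]
    t_ms = np.asarray(t_ms, float)
    win = (t_ms > BLINK_QC_WINDOW_MS[0]) & (t_ms <= BLINK_QC_WINDOW_MS[1])
    return np.isfinite(samples[:, win]).all(axis=1)


def qc_trials_and_subjects(subject: Exp2Subject):
    """Drop blink/missing-contaminated trials and decide subject inclusion.

    A subject stays in when (1) every color x location condition keeps at
    least one valid trial and (2) at least 50% of all trials are valid.
    Returns ``(kept_index, included)`` where ``kept_index`` is the integer
    index of surviving trials.
    """
    ok = trial_validity(subject.samples, subject.t_ms)
    _, base_ok = percent_signal_change(subject.samples, subject.t_ms)
    ok = ok & base_ok
    kept = np.flatnonzero(ok)
    frac = ok.mean() if len(ok) else 0.0
    covered = all(
        np.any(ok & (subject.colors == c) & (subject.locations == l))
        for c in COLORS for l in LOCATIONS)
    return kept, bool(covered and frac >= 0.5)


# ---------------------------------------------------------------------------
# PLRmin
# ---------------------------------------------------------------------------

def condition_waveform_and_plrmin(norm_epochs: np.ndarray, t_ms: np.ndarray):
    """Point-wise mean waveform over trials and its minimum in 0-2 s.

    ``norm_epochs`` is trials x time in percent signal change. Raises on an
    empty trial set (the subject-exclusion signal upstream).
    """
    norm_epochs = np.asarray(norm_epochs, float)
    if norm_epochs.ndim == 1:
        norm_epochs = norm_epochs[None, :]
    if len(norm_epochs) == 0:
        raise ValueError("no valid trials for this condition")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        wave = np.nanmean(norm_epochs, axis=0)
    win = (t_ms >= PLR_WINDOW_MS[0]) & (t_ms <= PLR_WINDOW_MS[1])
    plr_min = float(np.nanmin(wave[win]))
    return wave, plr_min


def plrmin_per_trial(norm_epochs: np.ndarray, t_ms: np.ndarray) -> np.ndarray:
    """Alternative metric: per-trial minima in the 0-2 s window."""
    norm_epochs = np.asarray(norm_epochs, float)
    if norm_epochs.ndim == 1:
        norm_epochs = norm_epochs[None, :]
    win = (t_ms >= PLR_WINDOW_MS[0]) & (t_ms <= PLR_WINDOW_MS[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmin(norm_epochs[:, win], axis=1)


def subject_plrmin_table(subject: Exp2Subject,
                         per_trial: bool = False) -> np.ndarray:
    """3 x 4 PLRmin array (colors x locations) for one included subject."""
    kept, included = qc_trials_and_subjects(subject)
    if not included:
        raise ValueError(f"subject {subject.subject} excluded by QC")
    norm, _ = percent_signal_change(subject.samples[kept], subject.t_ms)
    colors = subject.colors[kept]
    locations = subject.locations[kept]
    out = np.full((len(COLORS), len(LOCATIONS)), np.nan)
    for i, c in enumerate(COLORS):
        for j, l in enumerate(LOCATIONS):
            sel = (colors == c) & (locations == l)
            if per_trial:
                out[i, j] = float(np.mean(
                    plrmin_per_trial(norm[sel], subject.t_ms)))
            else:
                _, out[i, j] = condition_waveform_and_plrmin(
                    norm[sel], subject.t_ms)
    return out


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows sum to zero)."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, :i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
    return helmert / np.linalg.norm(helmert, axis=1, keepdims=True)


def _gg_epsilon(scores: np.ndarray, contrasts: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subjects x levels scores and an
    orthonormal contrast matrix over the levels."""
    y = scores @ contrasts.T
    c = np.cov(y, rowvar=False)
    c = np.atleast_2d(c)
    d = c.shape[0]
    tr = np.trace(c)
    denom = d * np.sum(c * c)
    if denom <= 0:
        return 1.0
    return float(min(1.0, max(tr**2 / denom, 1.0 / d)))


def rm_anova_3x4(plr_min: np.ndarray) -> pd.DataFrame:
    """Two-factor fully-within ANOVA on a subjects x colors x locations table.

    Returns one row per effect (color, location, color x location) with the
    uncorrected F and dfs, the Greenhouse-Geisser epsilon, the
    epsilon-corrected dfs and p value, and both partial and generalized eta
    squared. Subjects with any NaN cell are dropped with a warning.
    """
    y = np.asarray(plr_min, float)
    if y.ndim != 3:
        raise ValueError("expected subjects x colors x locations")
    keep = np.isfinite(y).all(axis=(1, 2))
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} subject(s) with "
                      "missing cells")
        y = y[keep]
    n, a, b = y.shape
    if n < 3:
        raise ValueError("need at least 3 complete subjects")

    grand = y.mean()
    s_m = y.mean(axis=(1, 2))              # subject means
    a_m = y.mean(axis=(0, 2))              # factor-A (color) means
    b_m = y.mean(axis=(0, 1))              # factor-B (location) means
    ab_m = y.mean(axis=0)                  # a x b cell means
    as_m = y.mean(axis=2)                  # n x a
    bs_m = y.mean(axis=1)                  # n x b

    ss_a = n * b * np.sum((a_m - grand) ** 2)
    ss_b = n * a * np.sum((b_m - grand) ** 2)
    ss_ab = n * np.sum((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2)
    ss_s = a * b * np.sum((s_m - grand) ** 2)
    ss_as = b * np.sum((as_m - a_m[None, :] - s_m[:, None] + grand) ** 2)
    ss_bs = a * np.sum((bs_m - b_m[None, :] - s_m[:, None] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_abs = ss_tot - (ss_a + ss_b + ss_ab + ss_s + ss_as + ss_bs)

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    eps_a = _gg_epsilon(as_m, ca)
    eps_b = _gg_epsilon(bs_m, cb)
    eps_ab = _gg_epsilon(y.reshape(n, a * b), np.kron(ca, cb))

    ss_subj_all = ss_s + ss_as + ss_bs + ss_abs
    rows = []
    for name, ss_eff, ss_err, df1, df2, eps in (
        ("color", ss_a, ss_as, a - 1, (a - 1) * (n - 1), eps_a),
        ("location", ss_b, ss_bs, b - 1, (b - 1) * (n - 1), eps_b),
        ("color * location", ss_ab, ss_abs,
         (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), eps_ab),
    ):
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        f = ms_eff / ms_err if ms_err > 0 else np.nan
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else np.nan
        p_gg = float(stats.f.sf(f, eps * df1, eps * df2)) if np.isfinite(f) else np.nan
        rows.append({
            "effect": name,
            "F": f,
            "df_num": df1,
            "df_den": df2,
            "p": p,
            "epsilon": eps,
            "df_num_gg": eps * df1,
            "df_den_gg": eps * df2,
            "p_gg": p_gg,
            "eta_sq_partial": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else np.nan,
            "eta_sq_generalized": ss_eff / (ss_eff + ss_subj_all) if ss_eff + ss_subj_all > 0 else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Planned difference scores
# ---------------------------------------------------------------------------

def difference_score_tests(plr_min: np.ndarray, q: float = 0.05,
                           pairs=(("top", "bottom"), ("left", "right"))
                           ) -> pd.DataFrame:
    """One-sample t tests of the six planned PLRmin difference scores.

    Per color, D = PLRmin(top) - PLRmin(bottom) and D = PLRmin(left) -
    PLRmin(right); each distribution over subjects is tested against zero
    and the six p values are BH-adjusted at level ``q``.
    """
    y = np.asarray(plr_min, float)
    if y.ndim != 3 or y.shape[1] != len(COLORS) or y.shape[2] != len(LOCATIONS):
        raise ValueError("expected subjects x 3 colors x 4 locations")
    keep = np.isfinite(y).all(axis=(1, 2))
    y = y[keep]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 included subjects")
    rows = []
    for i, color in enumerate(COLORS):
        for first, second in pairs:
            d = y[:, i, LOCATIONS.index(first)] - y[:, i, LOCATIONS.index(second)]
            if np.std(d, ddof=1) == 0:
                warnings.warn(f"degenerate variance for {color} "
                              f"{first}-{second}")
                t, p = (0.0, np.nan) if np.allclose(d, 0) else (np.nan, np.nan)
            else:
                t, p = stats.ttest_1samp(d, 0.0)
            rows.append({
                "color": color,
                "contrast": f"{first}-{second}",
                "mean_diff": float(np.mean(d)),
                "t": float(t),
                "df": n - 1,
                "p_raw": float(p) if p == p else np.nan,
            })
    df = pd.DataFrame(rows)
    mask, adj = bh_fdr(df["p_raw"].to_numpy(), q)
    df["p_fdr"] = adj
    df["significant"] = mask
    return df


def baseline_table(subject: Exp2Subject) -> np.ndarray:
    """3 x 4 mean pre-stimulus baseline (device units) over valid trials."""
    kept, _ = qc_trials_and_subjects(subject)
    samples = subject.samples[kept]
    t_ms = subject.t_ms
    base_win = (t_ms >= -EPOCH_PRE_MS) & (t_ms < 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        per_trial = np.nanmean(samples[:, base_win], axis=1)
    colors = subject.colors[kept]
    locations = subject.locations[kept]
    out = np.full((len(COLORS), len(LOCATIONS)), np.nan)
    for i, c in enumerate(COLORS):
        for j, l in enumerate(LOCATIONS):
            sel = (colors == c) & (locations == l)
            if sel.any():
                out[i, j] = float(np.mean(per_trial[sel]))
    return out
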