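import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pupilscene.plr import (COLORS, LOCATIONS, Exp2Subject,
                            condition_waveform_and_plrmin,
                            difference_score_tests, epoch_time_ms,
                            percent_signal_change, plrmin_per_trial,
                            qc_trials_and_subjects, rm_anova_3x4,
                            subject_plrmin_table, trial_validity)
from pupilscene.simulate import Exp2SimConfig, simulate_exp2

T_MS = epoch_time_ms()


def flat_epoch(level=1000.0):
    return np.full(T_MS.shape, level)


class TestPercentSignalChange:
    def test_flat_epoch_all_zero(self):
        norm, ok = percent_signal_change(flat_epoch(), T_MS)
        assert ok
        assert np.allclose(norm, 0.0)

    def test_trough_value(self):
        epoch = flat_epoch(1000.0)
        epoch[np.argmin(np.abs(T_MS - 900))] = 600.0
        norm, ok = percent_signal_change(epoch, T_MS)
        assert norm.min() == pytest.approx(-40.0)

    def test_all_missing_baseline_invalid(self):
        epoch = flat_epoch()
        epoch[T_MS < 0] = np.nan
        norm, ok = percent_signal_change(epoch, T_MS)
        assert not ok
        assert np.isnan(norm).all()

    def test_half_missing_baseline_still_ok(self):
        epoch = flat_epoch()
        base_idx = np.flatnonzero(T_MS < 0)
        epoch[base_idx[:len(base_idx) // 2]] = np.nan
        _, ok = percent_signal_change(epoch, T_MS)
        assert ok

    def test_nonpositive_baseline_invalid(self):
        _, ok = percent_signal_change(flat_epoch(0.0), T_MS)
        assert not ok

    def test_unit_rescaling_invariance(self, rng):
        epoch = 900.0 + 50.0 * rng.normal(size=T_MS.shape)
        a, _ = percent_signal_change(epoch, T_MS)
        b, _ = percent_signal_change(epoch * 3.7, T_MS)
        assert np.allclose(a, b, atol=1e-9)


def make_subject(n_trials=60, blink_trials=(), seed=0):
    rng = np.random.default_rng(seed)
    colors = np.repeat(COLORS, 20)[:n_trials]
    locations = np.tile(np.repeat(LOCATIONS, 5), 3)[:n_trials]
    samples = np.tile(flat_epoch(), (n_trials, 1))
    samples += rng.normal(0, 1.0, samples.shape)
    for i in blink_trials:
        win = (T_MS > 100) & (T_MS < 400)
        samples[i, win] = np.nan
    return Exp2Subject(subject="s", samples=samples, t_ms=T_MS,
                       colors=colors, locations=locations)


class TestQC:
    def test_all_valid_included(self):
        kept, included = qc_trials_and_subjects(make_subject())
        assert len(kept) == 60
        assert included

    def test_missing_condition_excludes(self):
        sub = make_subject()
        # void every blue-top trial (colors blue, location top)
        idx = np.flatnonzero((sub.colors == "blue") & (sub.locations == "top"))
        sub2 = make_subject(blink_trials=idx)
        kept, included = qc_trials_and_subjects(sub2)
        assert not included

    def test_under_half_valid_excludes(self):
        # keep >= 1 trial per condition but void 31 of 60 overall
        voided = []
        sub = make_subject()
        for c in COLORS:
            for l in LOCATIONS:
                idx = np.flatnonzero((sub.colors == c) & (sub.locations == l))
                voided.extend(idx[1:])  # leave exactly one per condition
        voided = voided[:31]
        sub2 = make_subject(blink_trials=voided)
        kept, included = qc_trials_and_subjects(sub2)
        assert len(kept) == 29
        assert not included

    def test_blink_in_window_voids_trial(self):
        sub = make_subject(blink_trials=[5])
        ok = trial_validity(sub.samples, sub.t_ms)
        assert not ok[5]
        assert ok.sum() == 59

    def test_missing_outside_window_is_fine(self):
        sub = make_subject()
        late = T_MS > 2000
        sub.samples[7, late] = np.nan
        ok = trial_validity(sub.samples, sub.t_ms)
        assert ok[7]


class TestPlrmin:
    def test_single_trial(self):
        epoch = flat_epoch(1000.0)
        epoch[np.argmin(np.abs(T_MS - 800))] = 700.0
        norm, _ = percent_signal_change(epoch, T_MS)
        wave, plr = condition_waveform_and_plrmin(norm, T_MS)
        assert plr == pytest.approx(-30.0)

    def test_pointwise_mean_of_two_trials(self):
        e1 = flat_epoch(1000.0)
        e2 = flat_epoch(1000.0)
        i = np.argmin(np.abs(T_MS - 1000))
        e1[i] = 700.0   # -30%
        e2[i] = 500.0   # -50%
        norm, _ = percent_signal_change(np.stack([e1, e2]), T_MS)
        _, plr = condition_waveform_and_plrmin(norm, T_MS)
        assert plr == pytest.approx(-40.0)

    def test_positive_waveform_min_still_returned(self):
        epoch = flat_epoch(1000.0) + 50.0 * (T_MS >= 0)
        norm, _ = percent_signal_change(epoch, T_MS)
        _, plr = condition_waveform_and_plrmin(norm, T_MS)
        assert plr >= 0.0

    def test_minimum_search_window_bounds(self):
        epoch = flat_epoch(1000.0)
        epoch[np.argmin(np.abs(T_MS - 2300))] = 100.0  # outside [0, 2000]
        norm, _ = percent_signal_change(epoch, T_MS)
        _, plr = condition_waveform_and_plrmin(norm, T_MS)
        assert plr == pytest.approx(0.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            condition_waveform_and_plrmin(np.empty((0, len(T_MS))), T_MS)

    def test_min_of_mean_at_least_mean_of_min(self, rng):
        for _ in range(20):
            epochs = rng.normal(-10, 5, size=(5, len(T_MS)))
            _, plr_mean = condition_waveform_and_plrmin(epochs, T_MS)
            per_trial = plrmin_per_trial(epochs, T_MS)
            assert plr_mean >= per_trial.mean() - 1e-12


def oracle_two_way_within(y):
    """Independent sum-of-squares decomposition by explicit loops."""
    n, a, b = y.shape
    grand = y.mean()
    ss_a = ss_b = ss_ab = ss_as = ss_bs = 0.0
    for j in range(a):
        ss_a += n * b * (y[:, j, :].mean() - grand) ** 2
    for k in range(b):
        ss_b += n * a * (y[:, :, k].mean() - grand) ** 2
    for j in range(a):
        for k in range(b):
            ss_ab += n * (y[:, j, k].mean() - y[:, j, :].mean()
                          - y[:, :, k].mean() + grand) ** 2
    for i in range(n):
        for j in range(a):
            ss_as += b * (y[i, j, :].mean() - y[:, j, :].mean()
                          - y[i].mean() + grand) ** 2
    for i in range(n):
        for k in range(b):
            ss_bs += a * (y[i, :, k].mean() - y[:, :, k].mean()
                          - y[i].mean() + grand) ** 2
    ss_s = sum(a * b * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_abs = ((y - grand) ** 2).sum() - (ss_a + ss_b + ss_ab + ss_s
                                         + ss_as + ss_bs)
    f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
    f_b = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (
        ss_abs / ((a - 1) * (b - 1) * (n - 1)))
    return f_a, f_b, f_ab


class TestRmAnova:
    def test_matches_loop_oracle_on_fixture(self):
        rng = np.random.default_rng(99)
        y = rng.normal(-40, 4, size=(4, 3, 4))
        tab = rm_anova_3x4(y)
        f_a, f_b, f_ab = oracle_two_way_within(y)
        assert tab.loc[0, "F"] == pytest.approx(f_a, abs=1e-8)
        assert tab.loc[1, "F"] == pytest.approx(f_b, abs=1e-8)
        assert tab.loc[2, "F"] == pytest.approx(f_ab, abs=1e-8)

    def test_matches_external_reference(self):
        """Frozen oracle: this exact dataset was run through R's anova.mlm
        (test='Spherical'), which reports the same Greenhouse-Geisser
        epsilons and corrected p values."""
        rng = np.random.default_rng(0)
        y = rng.normal(-40, 5, size=(6, 3, 4)) + rng.normal(0, 3, (6, 1, 1))
        tab = rm_anova_3x4(y).set_index("effect")
        assert tab.loc["color", "F"] == pytest.approx(0.5478, abs=2e-4)
        assert tab.loc["location", "F"] == pytest.approx(0.3689, abs=2e-4)
        assert tab.loc["color * location", "F"] == pytest.approx(1.7857, abs=2e-4)
        assert tab.loc["color", "epsilon"] == pytest.approx(0.9381, abs=2e-4)
        assert tab.loc["location", "epsilon"] == pytest.approx(0.5492, abs=2e-4)
        assert tab.loc["color * location", "epsilon"] == pytest.approx(0.4889, abs=2e-4)
        assert tab.loc["color", "p_gg"] == pytest.approx(0.58494, abs=2e-4)
        assert tab.loc["location", "p_gg"] == pytest.approx(0.66375, abs=2e-4)
        assert tab.loc["color * location", "p_gg"] == pytest.approx(0.19458, abs=2e-4)

    def test_additive_color_effect(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, size=(12, 3, 4))
        y[:, 2, :] -= 6.0  # strong blue effect
        tab = rm_anova_3x4(y).set_index("effect")
        assert tab.loc["color", "p_gg"] < 1e-4
        assert tab.loc["location", "p_gg"] > 0.01

    def test_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_3x4(np.zeros((2, 3, 4)))

    def test_nan_subject_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(5, 3, 4))
        y[0, 0, 0] = np.nan
        with pytest.warns(UserWarning, match="dropping"):
            tab = rm_anova_3x4(y)
        assert tab.loc[0, "df_den"] == 2 * 3  # n=4 -> (a-1)(n-1)=6

    def test_type_one_rate_smoke(self):
        # null with subject offsets only; acceptance runs 2000 reps
        rng = np.random.default_rng(2)
        reps, hits = 400, np.zeros(3)
        for _ in range(reps):
            y = rng.normal(0, 1, size=(15, 3, 4)) + rng.normal(0, 2, (15, 1, 1))
            tab = rm_anova_3x4(y)
            hits += (tab["p_gg"] < 0.05).to_numpy()
        rates = hits / reps
        assert np.all(rates < 0.09)
        assert np.all(rates > 0.01)


class TestDifferenceScores:
    def test_identical_conditions_all_zero(self):
        y = np.tile(np.random.default_rng(0).normal(-40, 3, (10, 1, 1)),
                    (1, 3, 4))
        with pytest.warns(UserWarning, match="degenerate"):
            tab = difference_score_tests(y)
        assert np.allclose(tab["mean_diff"], 0.0)
        assert np.allclose(tab["t"], 0.0)

    def test_six_rows_and_fdr_over_six(self):
        rng = np.random.default_rng(1)
        y = rng.normal(-40, 3, size=(15, 3, 4))
        tab = difference_score_tests(y)
        assert len(tab) == 6
        assert set(tab["color"]) == set(COLORS)
        # BH over exactly 6 p values
        from pupilscene.group_stats import bh_fdr
        mask, adj = bh_fdr(tab["p_raw"].to_numpy(), 0.05)
        assert np.array_equal(tab["significant"].to_numpy(), mask)
        assert np.allclose(tab["p_fdr"].to_numpy(), adj)

    def test_reversed_pair_flips_sign(self):
        rng = np.random.default_rng(2)
        y = rng.normal(-40, 3, size=(12, 3, 4))
        fwd = difference_score_tests(y)
        rev = difference_score_tests(
            y, pairs=(("bottom", "top"), ("right", "left")))
        assert np.allclose(fwd["t"].to_numpy(), -rev["t"].to_numpy())
        assert np.allclose(fwd["p_raw"].to_numpy(), rev["p_raw"].to_numpy())

    def test_injected_blue_top_effect_detected(self):
        cfg = Exp2SimConfig(noise_sd=0.0, blink_prob=0.0, between_sd=3.0,
                            within_sd=3.0, n_subjects=15, seed=11)
        subs, truth = simulate_exp2(cfg)
        y = np.stack([subject_plrmin_table(s) for s in subs])
        tab = difference_score_tests(y)
        sig = tab[tab["significant"]]
        assert ("blue", "top-bottom") in list(zip(sig["color"], sig["contrast"]))


class TestSubjectPlrminTable:
    def test_noiseless_recovers_amplitudes(self):
        cfg = Exp2SimConfig(noise_sd=0.0, blink_prob=0.0, between_sd=0.0,
                            within_sd=0.0, baseline_sd=0.0, n_subjects=3,
                            seed=0)
        subs, truth = simulate_exp2(cfg)
        for sub in subs:
            table = subject_plrmin_table(sub)
            assert np.allclose(table, truth["amplitudes"], atol=1e-9)

    def test_excluded_subject_raises(self):
        sub = make_subject(blink_trials=range(40))
        with pytest.raises(ValueError, match="excluded"):
            subject_plrmin_table(sub)
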