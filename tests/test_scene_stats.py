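import numpy as np
import pytest

from pupilscene.scene_stats import (GammaParams, GazeWindowStack,
                                    block_downsample, build_gaze_window_stack,
                                    extract_gaze_window, fit_gamma, gamma_lut,
                                    gamma_transform, gamma_transform_fn,
                                    nan_fraction_map, rgb_to_cielab)


class TestFitGamma:
    def test_recovers_exponent_on_exact_data(self):
        levels = np.arange(0, 256, 3)
        measured = (levels / 255.0) ** 2.2
        fit = fit_gamma(levels, measured)
        assert fit.gamma == pytest.approx(2.2, abs=0.01)
        assert fit.scale == pytest.approx(1.0, abs=0.01)

    def test_linear_data_gives_gamma_one(self):
        levels = np.arange(0, 256, 5)
        fit = fit_gamma(levels, levels / 255.0)
        assert fit.gamma == pytest.approx(1.0, abs=0.01)

    def test_scaled_data(self):
        levels = np.arange(0, 256, 3)
        measured = 120.0 * (levels / 255.0) ** 2.24  # cd/m^2 peak
        fit = fit_gamma(levels, measured)
        assert fit.gamma == pytest.approx(2.24, abs=0.01)
        assert fit.scale == pytest.approx(120.0, rel=0.01)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma([0, 255], [0.0, 1.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma([0, 100, 200, 255], [0, 0, 0, 0])

    def test_non_monotone_warns(self):
        levels = np.array([0, 60, 120, 180, 255])
        measured = np.array([0.0, 0.5, 0.1, 0.6, 1.0])
        with pytest.warns(UserWarning, match="non-monotone"):
            fit_gamma(levels, measured)


class TestGammaTransform:
    def test_endpoints(self):
        frame = np.array([[[0, 0, 0], [255, 255, 255]]], np.uint8)
        out = gamma_transform(frame)
        assert np.all(out[0, 0] == 0.0)
        assert np.allclose(out[0, 1], 1.0)

    def test_midpoint_value(self):
        frame = np.full((1, 1, 3), 128, np.uint8)
        out = gamma_transform(frame, GammaParams(2.22, 2.22, 2.22))
        expected = (128 / 255.0) ** 2.22
        assert out[0, 0, 0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.2165, abs=5e-4)

    def test_monotone_per_channel(self):
        ramp = np.arange(256, dtype=np.uint8).reshape(-1, 1, 1)
        frame = np.repeat(ramp, 3, axis=-1)
        out = gamma_transform(frame)
        for c in range(3):
            assert np.all(np.diff(out[:, 0, c]) > 0)

    def test_lut_matches_float_path(self, rng):
        frame = rng.integers(0, 256, (5, 7, 3), dtype=np.uint8)
        lut_out = gamma_transform(frame)
        float_out = gamma_transform(frame.astype(np.float64))
        assert np.allclose(lut_out, float_out, atol=1e-14)

    def test_transform_fn_has_lut(self):
        fn = gamma_transform_fn()
        assert fn.lut.shape == (256, 3)
        assert np.allclose(fn.lut, gamma_lut())


class TestCielab:
    def test_white_point(self):
        frame = np.full((1, 1, 3), 255, np.uint8)
        lab = rgb_to_cielab(frame)
        assert lab[0, 0, 0] == pytest.approx(100.0, abs=0.01)
        assert abs(lab[0, 0, 1]) < 0.5
        assert abs(lab[0, 0, 2]) < 0.5

    def test_black(self):
        lab = rgb_to_cielab(np.zeros((1, 1, 3), np.uint8))
        assert lab[0, 0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_blue_has_negative_bstar(self):
        frame = np.zeros((1, 1, 3), np.uint8)
        frame[0, 0, 2] = 255
        lab = rgb_to_cielab(frame)
        assert lab[0, 0, 2] < 0

    def test_gray_is_achromatic(self):
        for v in (32, 96, 160, 224):
            lab = rgb_to_cielab(np.full((1, 1, 3), v, np.uint8))
            assert abs(lab[0, 0, 1]) < 0.5
            assert abs(lab[0, 0, 2]) < 0.5

    def test_paper_polarity_flips_astar(self):
        frame = np.zeros((1, 1, 3), np.uint8)
        frame[0, 0, 0] = 255  # pure red
        cie = rgb_to_cielab(frame)
        flipped = rgb_to_cielab(frame, paper_polarity=True)
        assert cie[0, 0, 1] > 0           # CIE: red is positive a*
        assert flipped[0, 0, 1] == -cie[0, 0, 1]


class TestExtractWindow:
    def test_center_gaze_1080p_geometry(self):
        frame = np.ones((1080, 1920, 3))
        win = extract_gaze_window(frame, (960, 540), half=350)
        assert win.shape == (700, 700, 3)
        # columns fully inside; rows clipped by the 1080 px height
        nan_rows = np.isnan(win[..., 0]).all(axis=1)
        assert not np.isnan(win[..., 0]).all(axis=0).any()
        # rows covered: 540-350=190 .. 540+349=889 -> all inside => no NaN
        assert nan_rows.sum() == 0

    def test_top_edge_gaze_rows_clipped(self):
        frame = np.ones((1080, 1920, 3))
        win = extract_gaze_window(frame, (960, 100), half=350)
        nan_rows = np.isnan(win[..., 0]).all(axis=1)
        assert nan_rows.sum() == 250  # rows -250..-1 fall off-screen

    def test_corner_gaze_quarter_valid(self):
        frame = np.ones((1080, 1920, 3))
        win = extract_gaze_window(frame, (0, 0), half=350)
        valid = np.isfinite(win[..., 0])
        assert valid.sum() == 350 * 350
        assert valid.mean() == pytest.approx(0.25)
        assert valid[350:, 350:].all()

    def test_nan_gaze_all_nan(self):
        win = extract_gaze_window(np.ones((100, 100, 3)), (np.nan, 50), half=20)
        assert np.isnan(win).all()

    def test_off_screen_gaze_all_nan(self):
        win = extract_gaze_window(np.ones((100, 100, 3)), (150, 50), half=20)
        assert np.isnan(win).all()

    def test_gaze_lands_at_center_index(self):
        frame = np.zeros((100, 100, 1))
        frame[60, 40] = 7.0
        win = extract_gaze_window(frame, (40, 60), half=10)
        assert win[10, 10, 0] == 7.0


class TestBlockDownsample:
    def test_constant(self):
        win = np.full((700, 700, 3), 4.2)
        out = block_downsample(win, 10)
        assert out.shape == (70, 70, 3)
        assert np.allclose(out, 4.2)

    def test_half_nan_block(self):
        win = np.full((10, 10), 3.0)
        win[:5] = np.nan
        out = block_downsample(win, 10)
        assert out.shape == (1, 1)
        assert out[0, 0] == 3.0

    def test_all_nan_block(self):
        out = block_downsample(np.full((10, 10), np.nan), 10)
        assert np.isnan(out[0, 0])

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError):
            block_downsample(np.ones((700, 701)), 10)

    def test_matches_brute_force(self, rng):
        win = rng.normal(size=(40, 40, 2))
        win[rng.random(win.shape) < 0.3] = np.nan
        out = block_downsample(win, 10)
        for i in range(4):
            for j in range(4):
                for c in range(2):
                    block = win[i * 10:(i + 1) * 10, j * 10:(j + 1) * 10, c]
                    expected = (np.nanmean(block)
                                if np.isfinite(block).any() else np.nan)
                    got = out[i, j, c]
                    assert (np.isnan(got) and np.isnan(expected)) or \
                        got == pytest.approx(expected, abs=1e-12)


class TestWindowStack:
    def test_lut_fast_path_matches_generic(self, rng):
        frames = rng.integers(0, 256, (4, 60, 80, 3), dtype=np.uint8)
        gaze = np.column_stack([rng.uniform(0, 80, 4), rng.uniform(0, 60, 4)])
        fn = gamma_transform_fn()
        fast = build_gaze_window_stack(frames, gaze, half=20, factor=4,
                                       frame_transform=fn)
        slow = build_gaze_window_stack(frames.astype(np.int16), gaze, half=20,
                                       factor=4,
                                       frame_transform=lambda f:
                                       gamma_transform(f.astype(np.uint8)))
        assert np.allclose(fast.data, slow.data, equal_nan=True, atol=1e-14)

    def test_all_ones_gives_valid_fraction_pattern(self):
        frames = np.ones((1, 50, 50, 3))
        gaze = np.array([[0.0, 0.0]])
        stack = build_gaze_window_stack(frames, gaze, half=20, factor=4)
        vals = stack.data[0, ..., 0]
        # NaN-ignoring mean of ones is 1 wherever any cell is on-screen
        finite = np.isfinite(vals)
        assert np.all(vals[finite] == 1.0)
        assert finite[5:, 5:].all()
        assert not finite[:5].any()

    def test_nan_pattern_identical_across_channels(self, rng):
        frames = rng.integers(0, 256, (3, 40, 40, 3), dtype=np.uint8)
        gaze = np.array([[0.0, 0.0], [20.0, 20.0], [np.nan, np.nan]])
        stack = build_gaze_window_stack(frames, gaze, half=10, factor=2)
        nan0 = np.isnan(stack.data[..., 0])
        for c in (1, 2):
            assert np.array_equal(nan0, np.isnan(stack.data[..., c]))


class TestNanFractionMap:
    def test_no_nans(self):
        stack = GazeWindowStack(data=np.ones((4, 6, 6, 3)))
        assert np.all(nan_fraction_map(stack) == 0.0)

    def test_quarter(self):
        data = np.ones((4, 6, 6, 3))
        data[0, 2, 3, :] = np.nan
        stack = GazeWindowStack(data=data)
        frac = nan_fraction_map(stack)
        assert frac[2, 3] == 0.25
        assert frac.sum() == 0.25

    def test_corner_pinned_gaze_gradient(self):
        frames = np.ones((5, 60, 60, 3))
        gaze = np.tile([0.0, 0.0], (5, 1))  # top-left corner
        stack = build_gaze_window_stack(frames, gaze, half=20, factor=4)
        frac = nan_fraction_map(stack)
        assert frac[0, 0] == 1.0           # upper-left fully off-screen
        assert frac[-1, -1] == 0.0
        assert frac[0, :].mean() >= frac[-1, :].mean()
        assert frac[:, 0].mean() >= frac[:, -1].mean()
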