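"""Motion-correction schedules: averaging, limits, protocol checks, effectiveness."""

import numpy as np
import pandas as pd
import pytest

from cdti.io_formats import ImageSeries
from cdti.moco import average_by_direction, moco_avg, moco_naive
from cdti.motion_metric import track_series
from cdti.phantom import PhantomParams, make_phantom


def _series(frames, b_values, direction_index, average_index, spacing=(2.7, 2.7)):
    n = len(frames)
    meta = pd.DataFrame({
        "b_value": b_values,
        "direction_index": direction_index,
        "average_index": average_index,
        "acquisition_order": range(n),
    })
    return ImageSeries(np.asarray(frames, float), spacing, meta)


class TestAverageByDirection:
    def test_identical_frames_average_to_themselves(self):
        f = np.full((8, 6, 6), 3.3)
        s = _series(f, [500.0] * 8, [0] * 8, range(8))
        out = average_by_direction(s)
        assert out.n_frames == 1
        np.testing.assert_allclose(out.frames[0], 3.3)

    def test_arithmetic_mean_of_constant_frames(self):
        f = [np.full((4, 4), v) for v in range(1, 9)]
        s = _series(f, [500.0] * 8, [2] * 8, range(8))
        out = average_by_direction(s)
        np.testing.assert_allclose(out.frames[0], 4.5)
        assert out.frame_meta.loc[0, "average_index"] == 0
        assert out.frame_meta.loc[0, "direction_index"] == 2

    def test_singleton_group_unchanged(self):
        rng = np.random.default_rng(0)
        f = rng.random((3, 5, 5))
        s = _series(f, [50.0, 50.0, 500.0], [0, 1, 0], [0, 0, 0])
        out = average_by_direction(s)
        assert out.n_frames == 3
        # low shell first, then by direction
        np.testing.assert_array_equal(out.frames[0], f[0])
        np.testing.assert_array_equal(out.frames[2], f[2])


class TestProtocolChecks:
    def test_naive_first_frame_must_be_low_b(self):
        f = np.random.default_rng(1).random((4, 6, 6))
        s = _series(f, [500.0, 50.0, 500.0, 50.0], [0, 0, 1, 1], [0] * 4)
        with pytest.raises(ValueError, match="first acquired frame"):
            moco_naive(s)

    def test_avg_missing_low_b_direction_listed(self):
        f = np.random.default_rng(1).random((4, 6, 6))
        s = _series(f, [50.0, 50.0, 500.0, 500.0], [0, 1, 2, 3], [0] * 4)
        with pytest.raises(ValueError, match=r"direction indices \[2, 3\]"):
            moco_avg(s)


class TestZeroMotionLimits:
    def test_naive_fields_near_zero_and_averages_exact(self, small_still_phantom):
        _, series, truth = small_still_phantom
        sub = series.subset(np.arange(series.n_frames) < 15)  # 12 low + 3 high
        result = moco_naive(sub)
        for pair in result.fields:
            assert np.hypot(*pair.forward).mean() < 0.1
        direct = average_by_direction(sub)
        # per-(b, direction) means match up to the interpolation error of the
        # single warp (sub-percent at edge pixels, ~1e-4 on average)
        diff = np.abs(result.averaged_series.frames - direct.frames)
        assert diff.mean() < 1e-3
        assert diff.max() < 0.05 * direct.frames.max()

    def test_avg_reference_is_low_b_mean(self, small_still_phantom):
        _, series, truth = small_still_phantom
        result = moco_avg(series)
        low = series.frames[series.b_values == 50.0]
        ref_err = np.abs(result.reference - low.mean(axis=0)).mean()
        assert ref_err < 1e-3 * low.mean()  # 1e-3 relative in the mean
        assert result.stage3_fields is not None
        for pair in result.stage3_fields:
            assert np.hypot(*pair.forward).mean() < 0.1

    def test_averaged_frame_count_is_24_for_protocol_series(self, small_still_phantom):
        _, series, _ = small_still_phantom
        result = moco_avg(series)
        assert result.averaged_series.n_frames == 24
        counts = result.averaged_series.frame_meta.groupby("b_value").size()
        assert counts[50.0] == 12 and counts[500.0] == 12

    def test_corrected_series_metadata_identical(self, small_still_phantom):
        _, series, _ = small_still_phantom
        result = moco_naive(series)
        assert result.corrected_series.frames.shape == series.frames.shape
        pd.testing.assert_frame_equal(result.corrected_series.frame_meta, series.frame_meta)

    def test_signal_preserved_in_lv(self, small_still_phantom):
        """Registration must not create or destroy intensity beyond
        interpolation loss: total LV signal within 2% on a zero-motion phantom."""
        _, series, truth = small_still_phantom
        mask = truth.geometry.mask
        result = moco_avg(series)
        before = series.frames[:, mask].sum()
        after = result.corrected_series.frames[:, mask].sum()
        assert abs(after - before) / before < 0.02


class TestMotionCorrectionEffectiveness:
    def test_epicardium_sd_reduced(self, moving_phantom):
        """Free-breathing SD collapses after correction (> 75% reduction)."""
        _, series, truth = moving_phantom
        sd0 = track_series(series, truth.line_start, truth.line_end,
                           truth.window_center, truth.window_half_width).sd
        result = moco_naive(series)
        sd1 = track_series(result.corrected_series, truth.line_start, truth.line_end,
                           truth.window_center, truth.window_half_width).sd
        assert sd0 > 2.0
        assert sd1 < 0.25 * sd0

    def test_idempotence_of_naive(self):
        """Re-running on corrected output must find almost no motion left."""
        params = PhantomParams(snr=np.inf, motion_amplitude_px=5.0,
                               n_averages_high=1, seed=1)
        series, _ = make_phantom(params)
        sub = series.subset(np.arange(series.n_frames) < 14)
        once = moco_naive(sub)
        twice = moco_naive(once.corrected_series)
        mean_mag = np.mean([np.hypot(*p.forward).mean() for p in twice.fields])
        assert mean_mag < 0.1

    def test_five_slice_dataset_processed_slice_wise(self, small_still_phantom):
        """A 540-frame five-slice study is five independent 108-frame series;
        slice-wise correction keeps every frame."""
        params = PhantomParams(snr=np.inf, motion_amplitude_px=0.0, n_averages_high=8)
        total = 0
        for s in range(5):
            series, _ = make_phantom(params)
            series.slice_index = s
            total += series.n_frames
        assert total == 540
        # correcting one such slice preserves the frame count
        _, series, _ = small_still_phantom
        assert moco_naive(series).corrected_series.n_frames == series.n_frames
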