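import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wavebp.preprocess import (
    InputMode,
    SegmentSet,
    build_inputs,
    derivative,
    detrend_linear,
    scale_abp,
    segment,
    split_train_test,
)


class TestDetrend:
    def test_annihilates_affine(self):
        t = np.arange(50)
        np.testing.assert_allclose(detrend_linear(3.0 * t + 5.0), 0.0, atol=1e-9)

    def test_idempotent(self, rng):
        x = rng.normal(size=200).cumsum()
        once = detrend_linear(x)
        np.testing.assert_allclose(detrend_linear(once), once, atol=1e-9)

    def test_sine_plus_line(self):
        """Independent OLS fit subtracted by hand equals the detrender; the
        sine survives nearly unchanged."""
        t = np.arange(1250, dtype=float)
        sine = np.sin(2 * np.pi * t / 125.0)  # 10 full cycles
        x = sine + 0.01 * t + 2.0
        a, b = np.polyfit(t, x, 1)
        manual = x - (a * t + b)
        out = detrend_linear(x)
        np.testing.assert_allclose(out, manual, atol=1e-9)
        assert abs(np.polyfit(t, out, 1)[0]) < 1e-9
        assert np.corrcoef(out, sine)[0, 1] > 0.99

    def test_too_short(self):
        with pytest.raises(ValueError):
            detrend_linear([1.0])


class TestScaleAbp:
    def test_divides(self):
        np.testing.assert_array_equal(scale_abp([200.0]), [1.0])
        np.testing.assert_array_equal(scale_abp([0.0]), [0.0])

    def test_bad_divisor(self):
        with pytest.raises(ValueError):
            scale_abp([1.0], divisor=0.0)


class TestDerivative:
    def test_linear_ramp_gives_constant_slope(self):
        np.testing.assert_array_equal(derivative([0.0, 1.0, 2.0, 3.0]), 1.0)

    def test_constant_gives_zero(self):
        np.testing.assert_array_equal(derivative(np.full(10, 4.2)), 0.0)

    def test_quadratic_hand_evaluated(self):
        # X = t^2 at t=0..4: ends are one-sided differences, interior central
        out = derivative([0.0, 1.0, 4.0, 9.0, 16.0])
        np.testing.assert_array_equal(out, [1.0, 2.0, 4.0, 6.0, 7.0])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(2, 40), st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, n, a, b):
        rng = np.random.default_rng(n)
        x, y = rng.normal(size=(2, n))
        np.testing.assert_allclose(derivative(a * x + b * y),
                                   a * derivative(x) + b * derivative(y), atol=1e-9)

    def test_too_short(self):
        with pytest.raises(ValueError):
            derivative([1.0])


class TestSegment:
    def test_exactly_one_window(self, rng):
        s = segment([rng.normal(size=1024)], 1024, 0.75)
        assert s.n_segments == 1 and s.stride == 256

    def test_two_windows(self, rng):
        s = segment([rng.normal(size=1280)], 1024, 0.75)
        assert s.n_segments == 2
        np.testing.assert_array_equal(s.starts, [0, 256])

    def test_partial_trailing_window_dropped(self, rng):
        s = segment([rng.normal(size=1279)], 1024, 0.75)
        assert s.n_segments == 1

    def test_segment_content_matches_source(self, rng):
        x = rng.normal(size=600)
        s = segment([x], 256, 0.75)
        for k, start in enumerate(s.starts):
            np.testing.assert_array_equal(s.segments[k, :, 0], x[start:start + 256])

    def test_record_shorter_than_window(self, rng):
        with pytest.raises(ValueError):
            segment([rng.normal(size=1000)], 1024, 0.75)

    def test_non_integer_stride_rejected(self, rng):
        with pytest.raises(ValueError, match="stride"):
            segment([rng.normal(size=2048)], 1024, 0.7)  # 307.2 samples

    def test_inconsistent_starts_rejected(self, rng):
        with pytest.raises(ValueError, match="stride"):
            SegmentSet(segments=np.zeros((3, 8, 1)), starts=[0, 2, 5],
                       window_len=8, stride=2, channel_names=["x"])


class TestSplit:
    def _segset(self, n):
        return SegmentSet(segments=np.arange(n * 4.0).reshape(n, 4, 1),
                          starts=np.arange(n) * 2, window_len=4, stride=2,
                          channel_names=["x"])

    def test_ten_segments(self):
        tr, te = split_train_test(self._segset(10), 0.8)
        assert tr.n_segments == 8 and te.n_segments == 2

    def test_nine_segments_floor(self):
        tr, te = split_train_test(self._segset(9), 0.8)
        assert tr.n_segments == 7 and te.n_segments == 2

    def test_chronological_no_shuffle(self):
        s = self._segset(10)
        tr, te = split_train_test(s, 0.8)
        np.testing.assert_array_equal(tr.starts, s.starts[:8])
        np.testing.assert_array_equal(te.starts, s.starts[8:])
        np.testing.assert_array_equal(te.segments, s.segments[8:])

    def test_single_segment_cannot_split(self):
        with pytest.raises(ValueError):
            split_train_test(self._segset(1), 0.8)


class TestBuildInputs:
    def test_ppg_only_counts(self, eight_min_record):
        _, rec, _ = eight_min_record
        inputs, targets = build_inputs(rec, InputMode.PPG_ONLY)
        # 60000 samples, window 1024, stride 256
        assert inputs.n_segments == (60000 - 1024) // 256 + 1 == 231
        assert inputs.n_channels == 1 and targets.n_channels == 1
        assert inputs.channel_names == ["PPG"]

    def test_three_channel_mode(self, eight_min_record):
        _, rec, _ = eight_min_record
        inputs, _ = build_inputs(rec, "PPG_VPG_APG")
        assert inputs.n_channels == 3
        assert inputs.channel_names == ["PPG", "VPG", "APG"]

    def test_input_target_starts_identical(self, eight_min_record):
        _, rec, _ = eight_min_record
        inputs, targets = build_inputs(rec, InputMode.PPG_ONLY)
        np.testing.assert_array_equal(inputs.starts, targets.starts)

    def test_derivatives_computed_before_segmentation(self, eight_min_record):
        """VPG windows equal the windowed full-record derivative, including at
        window boundaries (no per-window edge effects)."""
        _, rec, _ = eight_min_record
        inputs, _ = build_inputs(rec, "PPG_VPG_APG")
        from wavebp.preprocess import detrend_linear, derivative
        vpg_full = derivative(detrend_linear(rec.ppg))
        k = 1  # a window that starts mid-record
        start = inputs.starts[k]
        np.testing.assert_allclose(inputs.segments[k, :, 1],
                                   vpg_full[start:start + 1024], atol=1e-12)

    def test_targets_are_scaled_abp(self, eight_min_record):
        _, rec, _ = eight_min_record
        _, targets = build_inputs(rec, InputMode.PPG_ONLY)
        assert targets.segments.min() >= 0.0 and targets.segments.max() <= 1.0
        np.testing.assert_allclose(targets.segments[0, :, 0], rec.abp[:1024] / 200.0)

    def test_too_short_record_rejected(self):
        from wavebp.records import SignalRecord
        rec = SignalRecord("s", 125.0, np.zeros(512), np.full(512, 100.0))
        with pytest.raises(ValueError):
            build_inputs(rec, InputMode.PPG_ONLY)
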