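import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organchip.beats import (BeatParams, BeatSeries, analyze_trace, beat_rate,
                             detect_beats, detect_cessation, windowed_rates)
from organchip.errors import ArgumentError
from organchip.motion import MotionTrace, compute_motion_trace
from organchip.synth import VideoTruth, generate_beating_video

from oracles import brute_force_peaks


def trace_of(values, fps=30.0):
    return MotionTrace(counts=np.asarray(values, dtype=float), fps=fps, tau_used=1.0)


class TestDetectBeats:
    def test_constant_trace_has_no_peaks(self):
        assert detect_beats(trace_of(np.full(100, 7.0))).n_peaks == 0

    def test_clean_pulse_train_recovers_every_pulse(self):
        # 1 Hz raised-cosine pulse train, 30 s at 30 fps; a small phase
        # offset avoids exact sample ties at bump tops (plateaus are not
        # strict local maxima by definition)
        t = np.arange(0, 30, 1 / 30.0)
        x = np.maximum(0.0, np.sin(2 * np.pi * (t - 0.013))) ** 2 * 100
        series = detect_beats(trace_of(x))
        assert series.n_peaks == 30
        np.testing.assert_allclose(np.diff(series.peak_times_s), 1.0, atol=0.05)

    @given(st.lists(st.integers(min_value=0, max_value=30), min_size=3, max_size=200),
           st.sampled_from([10.0, 30.0]))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_exhaustive_oracle(self, values, fps):
        params = BeatParams()
        got = detect_beats(trace_of(values, fps), params).indices.tolist()
        expected = brute_force_peaks(values, fps, params.prominence_frac,
                                     params.refractory_s)
        assert got == expected

    def test_peak_set_invariant_to_positive_scaling(self, rng):
        x = rng.integers(0, 50, size=150).astype(float)
        a = detect_beats(trace_of(x)).indices
        b = detect_beats(trace_of(x * 37.5)).indices
        np.testing.assert_array_equal(a, b)

    def test_empty_trace_rejected(self):
        with pytest.raises(ArgumentError):
            detect_beats(trace_of([]))


class TestBeatRate:
    def test_uniform_spacing(self):
        series = BeatSeries(np.arange(11.0), np.ones(11))
        m = beat_rate(series, duration_s=11.0)
        assert m.bpm == pytest.approx(60.0)
        assert m.ibi_cv == 0.0
        assert m.n_peaks == 11

    def test_irregular_spacing_arithmetic(self):
        series = BeatSeries(np.array([0.0, 0.5, 1.5]), np.ones(3))
        m = beat_rate(series, duration_s=2.0)
        assert m.ibi_mean_s == pytest.approx(0.75)
        assert m.bpm == pytest.approx(80.0)

    def test_fewer_than_two_peaks_gives_zero_bpm(self):
        m = beat_rate(BeatSeries(np.array([1.0]), np.array([5.0])), duration_s=10.0)
        assert m.bpm == 0.0
        assert m.n_peaks == 1

    def test_negative_duration_rejected(self):
        with pytest.raises(ArgumentError):
            beat_rate(BeatSeries(np.array([]), np.array([])), duration_s=-1.0)

    def test_recovery_from_noisy_90bpm_video(self):
        seq, truth = generate_beating_video(
            VideoTruth(bpm_trajectory=90.0, noise_sd=2.0, seed=11))
        trace = compute_motion_trace(seq)
        _, metrics = analyze_trace(trace)
        assert metrics.bpm == pytest.approx(90.0, abs=2.0)
        assert abs(metrics.n_peaks - truth.n_pulses) <= 1


class TestCessation:
    def test_flat_noise_trace_is_ceased(self, rng):
        x = rng.poisson(20, size=900).astype(float)
        trace = trace_of(x)
        series = detect_beats(trace)
        assert detect_cessation(trace, series) is True

    def test_steady_beating_not_ceased(self):
        seq, _ = generate_beating_video(VideoTruth(bpm_trajectory=60.0, seed=13))
        trace = compute_motion_trace(seq)
        series = detect_beats(trace)
        assert detect_cessation(trace, series) is False

    def test_beating_then_silence_triggers_trailing_window(self):
        def rate(t):
            return 60.0 if t < 20.0 else 0.0

        seq, _ = generate_beating_video(
            VideoTruth(bpm_trajectory=rate, duration_s=35.0, seed=17))
        trace = compute_motion_trace(seq)
        series, metrics = analyze_trace(trace)
        assert metrics.ceased is True
        assert metrics.bpm == 0.0


class TestWindowedRates:
    def test_constant_rate_across_windows(self):
        seq, _ = generate_beating_video(VideoTruth(bpm_trajectory=60.0, seed=19))
        trace = compute_motion_trace(seq)
        rates = windowed_rates(trace, window_s=10.0)
        assert len(rates) == 3
        for _, bpm in rates:
            assert bpm == pytest.approx(60.0, abs=2.0)

    def test_step_change_detected_per_window(self):
        def rate(t):
            return 60.0 if t < 15.0 else 90.0

        seq, _ = generate_beating_video(
            VideoTruth(bpm_trajectory=rate, duration_s=30.0, seed=23))
        trace = compute_motion_trace(seq)
        rates = windowed_rates(trace, window_s=10.0)
        assert rates[0][1] == pytest.approx(60.0, abs=3.0)
        assert rates[-1][1] == pytest.approx(90.0, abs=3.0)

    def test_trace_without_peaks_gives_zero_everywhere(self):
        trace = trace_of(np.full(900, 3.0))
        for _, bpm in windowed_rates(trace, window_s=10.0):
            assert bpm == 0.0

    def test_window_longer_than_trace_collapses_to_one(self):
        seq, _ = generate_beating_video(
            VideoTruth(bpm_trajectory=60.0, duration_s=5.0, seed=29))
        trace = compute_motion_trace(seq)
        rates = windowed_rates(trace, window_s=60.0)
        assert len(rates) == 1

    def test_window_below_refractory_limit_rejected(self):
        with pytest.raises(ArgumentError):
            windowed_rates(trace_of(np.zeros(100)), window_s=0.3)
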