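"""Calcium-trace metrics: normalization, AUC, ratios, peaks, durations."""
import numpy as np
import pytest

from larvaquant import (
    DegenerateInputError,
    EpochDef,
    FluorescenceTrace,
    LarvaQuantError,
    NormalizedTrace,
    UndefinedRatioError,
    amplitude_histogram,
    average_across_rois,
    detect_peaks,
    frames_to_seconds,
    mean_peak_count,
    normalize_dff,
    post_pre_ratio,
    response_duration,
    response_onset,
    trapezoid_auc,
)
from larvaquant.calcium import frames_to_seconds_reported

from _oracles import oracle_peaks


def trace(values, rate=5.2, roi="t"):
    return FluorescenceTrace(roi_id=roi, rate_hz=rate, values=values)


def ntrace(values, rate=5.2, roi="t"):
    return NormalizedTrace(roi_id=roi, rate_hz=rate, values=np.asarray(values, float))


def gaussian_bump(n, center, amp, sigma):
    x = np.arange(n, dtype=float)
    return amp * np.exp(-((x - center) ** 2) / (2 * sigma**2))


class TestFramesToSeconds:
    @pytest.mark.parametrize(
        "n,rate,expected",
        [
            (600, 5.2, 115.4),   # shock-paradigm baseline block
            (15, 2.6, 5.8),      # pre/post AUC window
            (200, 2.6, 76.9),    # spontaneous block of an optogenetic session
            (20, 2.6, 7.7),      # stimulation block
            (150, 2.6, 57.7),    # recovery block
            (370, 2.6, 142.3),   # whole optogenetic session
        ],
    )
    def test_reported_session_durations(self, n, rate, expected):
        assert frames_to_seconds_reported(n, rate) == expected

    def test_zero_frames(self):
        assert frames_to_seconds(0, 7.0) == 0.0

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(LarvaQuantError):
            frames_to_seconds(10, 0)


class TestNormalizeDff:
    def test_minmax_formula(self):
        out = normalize_dff(trace([2, 4, 10]))
        np.testing.assert_allclose(out.values, [0, 0.25, 1])

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normalize_dff(trace([5, 5, 5]))

    def test_matches_elementwise_oracle_and_attains_bounds(self, rng):
        for _ in range(20):
            v = rng.normal(100, 15, size=200)
            out = normalize_dff(trace(v))
            expected = (v - v.min()) / (v.max() - v.min())
            np.testing.assert_allclose(out.values, expected, atol=1e-12)
            assert out.values.min() == 0.0
            assert out.values.max() == 1.0

    def test_affine_invariance(self, rng):
        v = rng.normal(0, 1, size=150)
        base = normalize_dff(trace(v)).values
        shifted = normalize_dff(trace(7.5 + 3.2 * v)).values
        np.testing.assert_allclose(shifted, base, atol=1e-12)

    def test_missing_frames_stay_missing(self):
        v = np.array([1.0, np.nan, 3.0, 5.0])
        out = normalize_dff(trace(v))
        assert np.isnan(out.values[1])
        np.testing.assert_allclose(out.values[[0, 2, 3]], [0, 0.5, 1])


class TestAverageAcrossRois:
    def test_single_trace_is_itself_with_zero_sd(self, rng):
        t = ntrace(rng.uniform(size=50))
        mean, sd = average_across_rois([t])
        np.testing.assert_array_equal(mean, t.values)
        np.testing.assert_array_equal(sd, np.zeros(50))

    def test_complementary_pair_averages_to_half(self, rng):
        v = rng.uniform(size=80)
        mean, _ = average_across_rois([ntrace(v), ntrace(1 - v)])
        np.testing.assert_allclose(mean, 0.5)

    def test_matches_per_frame_loop(self, rng):
        traces = [ntrace(rng.uniform(size=30)) for _ in range(5)]
        mean, sd = average_across_rois(traces)
        for f in range(30):
            col = [t.values[f] for t in traces]
            assert mean[f] == pytest.approx(np.mean(col), abs=1e-12)
            assert sd[f] == pytest.approx(np.std(col), abs=1e-12)

    def test_rejects_mismatched_lengths(self):
        with pytest.raises(LarvaQuantError):
            average_across_rois([ntrace([0, 1]), ntrace([0, 0.5, 1])])


class TestTrapezoidAuc:
    def test_constant_closed_form(self):
        t = ntrace(np.full(20, 0.4))
        assert trapezoid_auc(t, EpochDef(0, 20)) == pytest.approx(0.4 * 19)

    def test_two_frames(self):
        assert trapezoid_auc(ntrace([0.0, 1.0]), EpochDef(0, 2)) == 0.5

    def test_matches_summation_oracle(self, rng):
        v = rng.uniform(size=40)
        t = ntrace(v)
        s, e = 10, 25
        expected = sum((v[i] + v[i + 1]) / 2 for i in range(s, e - 1))
        assert trapezoid_auc(t, EpochDef(s, e)) == pytest.approx(expected, abs=1e-12)

    def test_additivity_with_bridge(self, rng):
        v = rng.uniform(size=60)
        t = ntrace(v)
        left = trapezoid_auc(t, EpochDef(0, 30))
        right = trapezoid_auc(t, EpochDef(30, 60))
        bridge = (v[29] + v[30]) / 2
        total = trapezoid_auc(t, EpochDef(0, 60))
        assert left + right + bridge == pytest.approx(total, abs=1e-10)

    def test_missing_frames_are_bridged(self):
        v = np.array([0.0, np.nan, 1.0])
        # trapezoid joins frames 0 and 2 directly: (0+1)/2 * 2
        assert trapezoid_auc(ntrace(v), EpochDef(0, 3)) == pytest.approx(1.0)

    def test_epoch_outside_trace(self):
        with pytest.raises(LarvaQuantError):
            trapezoid_auc(ntrace([0, 1]), EpochDef(0, 5))


class TestPostPreRatio:
    def test_identical_windows_give_unity(self):
        v = np.concatenate([np.tile([1.0, 2.0, 3.0], 10)] * 2)
        assert post_pre_ratio(trace(v), 30, window=15) == pytest.approx(1.0)

    def test_zero_pre_auc_is_undefined(self):
        v = np.concatenate([np.zeros(20), np.ones(20)])
        with pytest.raises(UndefinedRatioError):
            post_pre_ratio(trace(v), 20, window=15)

    def test_missing_switch_frames_are_skipped(self):
        v = np.concatenate([np.full(20, 2.0), np.full(20, 6.0)])
        v[20] = np.nan  # switch-latency gap at onset
        assert post_pre_ratio(trace(v), 20, window=15) == pytest.approx(3.0)

    def test_insufficient_frames(self):
        with pytest.raises(LarvaQuantError):
            post_pre_ratio(trace(np.ones(20)), 5, window=15)


class TestDetectPeaks:
    def test_flat_trace_has_no_peaks(self):
        t = ntrace(np.zeros(100))
        assert detect_peaks(t).count == 0

    def test_two_gaussian_bumps(self):
        v = gaussian_bump(400, 100, 0.6, 8) + gaussian_bump(400, 300, 0.6, 8)
        assert detect_peaks(ntrace(v)).count == 2

    def test_subthreshold_bump_rejected(self):
        v = gaussian_bump(400, 200, 0.2, 8)
        assert detect_peaks(ntrace(v)).count == 0

    def test_matches_exhaustive_oracle_on_random_traces(self, rng):
        """Implementation vs exhaustive local-maxima + textbook prominence."""
        for _ in range(100):
            n = int(rng.integers(60, 300))
            v = np.clip(rng.normal(0.3, 0.2, size=n).cumsum() % 1.0, 0, 1)
            got = detect_peaks(ntrace(v), 0.3, 10).frames.tolist()
            assert got == oracle_peaks(v, 0.3, 10)

    def test_matches_oracle_on_constructed_traces(self):
        for amps, sig in [((0.35, 0.9), 6), ((0.5, 0.5, 0.5), 12)]:
            v = sum(
                gaussian_bump(600, 100 + 150 * i, a, sig)
                for i, a in enumerate(amps)
            )
            got = detect_peaks(ntrace(v), 0.3, 10).frames.tolist()
            assert got == oracle_peaks(v, 0.3, 10)

    def test_plateau_resolves_to_leftmost_sample(self):
        v = np.zeros(60)
        v[25:30] = 0.8  # 5-sample plateau
        peaks = detect_peaks(ntrace(v), 0.3, 2)
        assert peaks.frames.tolist() == [25]

    def test_threshold_monotonicity(self, rng):
        v = np.abs(np.sin(np.linspace(0, 20, 500))) * rng.uniform(0.5, 1.0, 500)
        t = ntrace(v)
        base = detect_peaks(t, 0.2, 5).count
        assert detect_peaks(t, 0.4, 5).count <= base
        assert detect_peaks(t, 0.2, 15).count <= base

    def test_too_short_trace(self):
        with pytest.raises(LarvaQuantError):
            detect_peaks(ntrace(np.zeros(8)), 0.3, 10)


class TestMeanPeakCount:
    def test_mean_over_neurons(self):
        def ps(k):
            v = sum(gaussian_bump(500, 60 + 60 * i, 0.8, 6) for i in range(k))
            return detect_peaks(ntrace(v), 0.3, 5)

        assert mean_peak_count([ps(4)]) == 4
        assert mean_peak_count([ps(3), ps(5)]) == 4

    def test_empty_larva(self):
        with pytest.raises(LarvaQuantError):
            mean_peak_count([])


class TestResponseOnset:
    def test_flat_trace_has_no_onset(self):
        assert response_onset(ntrace(np.zeros(100))) is None

    def test_single_bump_onset_at_peak(self):
        v = gaussian_bump(400, 120, 0.8, 8)
        assert response_onset(ntrace(v)) == oracle_peaks(v, 0.2, 10)[0]

    def test_two_bumps_takes_the_earlier(self):
        v = gaussian_bump(500, 150, 0.6, 8) + gaussian_bump(500, 350, 0.9, 8)
        onset = response_onset(ntrace(v))
        assert abs(onset - 150) <= 1


class TestResponseDuration:
    def test_trace_at_baseline_returns_zero(self):
        v = np.full(300, 0.2)
        dur, censored = response_duration(ntrace(v), 150, 100)
        assert dur == 0.0 and not censored

    def test_rectangular_elevation_closed_form(self):
        v = np.zeros(400)
        v[200:252] = 0.9  # 52 elevated frames at 5.2 Hz
        dur, censored = response_duration(ntrace(v, rate=5.2), 200, 100)
        assert dur == pytest.approx(10.0)
        assert not censored

    def test_never_returning_trace_is_censored(self):
        v = np.concatenate([np.zeros(150), np.ones(100)])
        dur, censored = response_duration(ntrace(v, rate=5.0), 150, 100)
        assert censored
        assert dur == pytest.approx((250 - 1 - 150) / 5.0)

    def test_duration_bounds(self, rng):
        for _ in range(20):
            v = rng.uniform(size=400)
            dur, _ = response_duration(ntrace(v, rate=5.2), 200, 100)
            assert 0 <= dur <= (400 - 200) / 5.2

    def test_shock_too_early(self):
        with pytest.raises(LarvaQuantError):
            response_duration(ntrace(np.zeros(200)), 50, 100)


class TestAmplitudeHistogram:
    def test_constant_zero_mass_in_first_bin(self):
        counts, _ = amplitude_histogram(
            [ntrace(np.zeros(50))], EpochDef(0, 50), 0.1
        )
        assert counts[0] == 50 and counts[1:].sum() == 0

    def test_uniform_ramp_splits_evenly(self):
        v = np.linspace(0, 1, 100)
        counts, edges = amplitude_histogram([ntrace(v)], EpochDef(0, 100), 0.5)
        assert len(counts) == 2
        assert abs(int(counts[0]) - int(counts[1])) <= 1

    def test_matches_counting_oracle(self, rng):
        traces = [ntrace(rng.uniform(size=60)) for _ in range(3)]
        counts, edges = amplitude_histogram(traces, EpochDef(10, 50), 0.25)
        pooled = np.concatenate([t.values[10:50] for t in traces])
        brute = [
            np.sum((pooled >= edges[i]) & (
                (pooled < edges[i + 1]) if i < len(counts) - 1
                else (pooled <= edges[i + 1])
            ))
            for i in range(len(counts))
        ]
        assert counts.tolist() == brute

    def test_peak_mode(self):
        v = gaussian_bump(400, 100, 0.9, 8) + gaussian_bump(400, 300, 0.5, 8)
        counts, _ = amplitude_histogram(
            [ntrace(v)], EpochDef(0, 400), 0.25, mode="peak",
            min_prominence=0.3, min_width=5,
        )
        assert counts.sum() == 2
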