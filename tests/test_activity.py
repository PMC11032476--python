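"""Detrending, binarization, activity statistics and spike magnitudes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from calcomm import (
    ActivityMatrix,
    SpikeBinarizer,
    activation_rate,
    binarize,
    build_activity,
    detrend,
    local_density,
    normalize,
    spike_magnitude_zscore,
)
from calcomm.activity import runs_of
from calcomm.synthetic import null_config, simulate


class TestDetrend:
    def test_rectangular_pulse_recovered_at_unit_height(self):
        trace = np.zeros(100)
        trace[50:52] = 1.0  # width-2 pulse survives the 3-point median
        out = detrend(trace)
        assert out.max() == pytest.approx(1.0)
        assert np.argmax(out) in (50, 51)
        assert out[:45].max() < 0.05

    def test_slow_ramp_is_removed(self):
        out = detrend(np.linspace(0, 1, 120))
        # residual stays below the binarization threshold everywhere
        assert (out < 0.4).all() or out.max() == 0

    def test_all_zero_trace_stays_zero(self):
        np.testing.assert_array_equal(detrend(np.zeros(50)), 0.0)

    def test_even_window_incremented_with_warning(self):
        with pytest.warns(UserWarning, match="even"):
            detrend(np.random.default_rng(0).random(60), smooth_k=4)

    def test_long_window_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            detrend(np.random.default_rng(0).random(10), bias_k=25)


class TestBinarize:
    def test_simple_thresholding(self):
        active = binarize(np.array([0.0, 0.5, 0.6, 0.1]))
        np.testing.assert_array_equal(active, [False, True, True, False])

    def test_all_below_bin_thr_inactive(self):
        assert not binarize(np.full(10, 0.39)).any()

    def test_peak_filter_suppresses_weak_runs(self):
        detrended = np.array([0.0, 0.5, 0.6, 0.0, 0.45, 0.45, 0.0])
        active = binarize(detrended, peak_thr=0.55, bin_thr=0.4)
        np.testing.assert_array_equal(active, [0, 1, 1, 0, 0, 0, 0])

    @given(
        detrended=arrays(float, 30, elements=st.floats(0, 1)),
        thr=st.tuples(st.floats(0.1, 0.9), st.floats(0.1, 0.9)),
    )
    def test_monotone_in_bin_thr(self, detrended, thr):
        """Raising bin_thr never adds active frames."""
        lo, hi = min(thr), max(thr)
        a_hi = np.atleast_1d(binarize(detrended, bin_thr=hi))
        a_lo = np.atleast_1d(binarize(detrended, bin_thr=lo))
        assert not (a_hi & ~a_lo).any()

    def test_onsets_are_run_starts(self):
        active = binarize(np.array([0.0, 0.5, 0.5, 0.0, 0.9, 0.0]))
        np.testing.assert_array_equal([s for s, _ in runs_of(active)], [1, 4])
        # and the fitted binarizer's onsets are exactly its runs' starts
        rng = np.random.default_rng(0)
        trace = np.zeros(120)
        trace[[30, 31, 70, 71, 100]] = 1.0
        sb = SpikeBinarizer().fit((trace + rng.normal(0, 0.02, 120))[None, :])
        runs = runs_of(sb.active_[0])
        assert len(runs) >= 2
        np.testing.assert_array_equal(sb.onsets_[0], [s for s, _ in runs])

    def test_constant_cell_has_no_active_frames(self):
        with pytest.warns(UserWarning):
            norm = normalize(np.vstack([np.full(60, 7.0), np.random.default_rng(3).random(60)]))
        act = build_activity(norm)
        assert not act.active[0].any()
        assert len(act.onsets[0]) == 0


class TestActivationRate:
    def test_rate_arithmetic(self):
        active = np.zeros((1, 40), dtype=bool)
        active[0, [2, 10, 20, 30]] = True  # 4 isolated onsets
        am = ActivityMatrix(active=active, detrended=active.astype(float),
                            onsets=[np.array([2, 10, 20, 30])])
        per_cell, mean = activation_rate(am, frame_interval=3.0)  # 2 min recording
        assert per_cell[0] == pytest.approx(2.0)
        assert mean == pytest.approx(2.0)

    def test_zero_rate_without_onsets(self):
        am = ActivityMatrix(np.zeros((2, 10), bool), np.zeros((2, 10)), [np.array([], int)] * 2)
        assert activation_rate(am, 1.0)[1] == 0.0

    def test_zero_duration_rejected(self):
        am = ActivityMatrix(np.zeros((1, 5), bool), np.zeros((1, 5)), [np.array([], int)])
        with pytest.raises(ValueError):
            activation_rate(am, 0.0)

    def test_poisson_simulation_recovers_rate(self):
        """λ = 1/min over 60 cells x 10 min gives a mean rate near 1
        (law of large numbers on the ground-truth onsets)."""
        cfg = null_config(11).replace(n_cells=60, duration=600.0)
        rec, gt = simulate(cfg)
        onsets = gt.onset_frames(rec.n_cells, rec.frame_interval, rec.n_frames)
        active = np.zeros((rec.n_cells, rec.n_frames), bool)
        for c, f in enumerate(onsets):
            active[c, f] = True
        am = ActivityMatrix(active=active, detrended=active.astype(float), onsets=onsets)
        _, mean = activation_rate(am, rec.frame_interval)
        assert mean == pytest.approx(1.0, abs=0.12)


class TestLocalDensity:
    def test_pair_inside_window(self):
        per, mean = local_density(np.array([[0.0, 0.0], [5.0, 0.0]]), window=14.0)
        np.testing.assert_array_equal(per, [1, 1])

    def test_diagonal_pair_outside_half_window(self):
        per, _ = local_density(np.array([[0.0, 0.0], [10.0, 10.0]]), window=14.0)
        np.testing.assert_array_equal(per, [0, 0])

    def test_uniform_field_matches_expectation(self):
        rng = np.random.default_rng(5)
        means = []
        for _ in range(20):
            pos = rng.uniform(0, 100, size=(100, 2))
            means.append(local_density(pos, 14.0)[1])
        # E = 99 * (14/100)^2 ~ 1.94, up to edge effects (which lower it)
        assert np.mean(means) == pytest.approx(1.94, abs=0.35)


class TestSpikeMagnitude:
    def _activity_for(self, active_row):
        active = np.atleast_2d(active_row).astype(bool)
        onsets = [np.array([s for s, _ in runs_of(r)]) for r in active]
        return ActivityMatrix(active=active, detrended=active.astype(float), onsets=onsets)

    def test_zscore_of_constructed_spike(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0.2, 0.05, size=(1, 200))
        values[0, 100:103] = [0.5, 0.7, 0.4]
        active = np.zeros(200, bool)
        active[100:103] = True
        z = spike_magnitude_zscore(values, self._activity_for(active))
        assert z[0] == pytest.approx((0.7 - 0.2) / 0.05, rel=0.25)

    def test_peak_at_background_mean_scores_zero(self):
        values = np.tile([0.19, 0.21], 50)[None, :]
        values[0, 50:52] = 0.2
        active = np.zeros(100, bool)
        active[50:52] = True
        z = spike_magnitude_zscore(values, self._activity_for(active))
        assert z[0] == pytest.approx(0.0, abs=0.2)

    def test_continuous_activity_is_flagged(self):
        values = np.full((1, 50), 0.5)
        z = spike_magnitude_zscore(values, self._activity_for(np.ones(50, bool)))
        assert np.isnan(z[0])

    def test_guard_band_excludes_three_frames(self):
        # frames within 3 of the run must not contribute to the background
        values = np.zeros((1, 30))
        active = np.zeros(30, bool)
        active[10:13] = True
        values[0, 10:13] = 1.0
        values[0, [7, 8, 9, 13, 14, 15]] = 5.0  # guard frames: huge, must be ignored
        values[0, :7] = np.tile([0.1, 0.3], 4)[:7]
        values[0, 16:] = np.tile([0.1, 0.3], 7)
        z = spike_magnitude_zscore(values, self._activity_for(active))
        bg = np.r_[values[0, :7], values[0, 16:]]
        expected = (1.0 - bg.mean()) / bg.std(ddof=1)
        assert z[0] == pytest.approx(expected)


class TestOnsetRecovery:
    def test_recall_and_precision_on_simulated_ground_truth(self):
        """At SNR 5 and default thresholds, >= 90% of true spikes are found
        and >= 90% of detected onsets are real."""
        tp = fp = fn = 0
        for i in range(5):
            cfg = null_config(3000 + i).replace(baseline_sd=4.0)  # amplitude 20 -> SNR 5
            rec, gt = simulate(cfg)
            act = build_activity(normalize(rec))
            true = gt.onset_frames(rec.n_cells, rec.frame_interval, rec.n_frames)
            for c in range(rec.n_cells):
                active_frames = np.flatnonzero(act.active[c])
                for f in true[c]:
                    if active_frames.size and np.abs(active_frames - f).min() <= 2:
                        tp += 1
                    else:
                        fn += 1
                for onset in act.onsets[c]:
                    if true[c].size == 0 or np.abs(true[c] - onset).min() > 2:
                        fp += 1
        assert tp / (tp + fn) >= 0.9
        assert tp / (tp + fp) >= 0.9
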