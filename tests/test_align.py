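"""Trial filters, fixed-window extraction, and three-anchor warping."""
import numpy as np
import pytest

from cuephot.align import (AlignmentError, SegmentLayout, Trial,
                           build_daily_heatmap, extract_peri_event,
                           filter_incorrect_events, filter_rewarded_trials,
                           select_key_days, warp_trial)
from cuephot.behavior import SessionSummary, detect_acquisition
from cuephot.events import EventCode, Phase
from cuephot.preprocess import Channel, ProcessedTrace
from tests.conftest import make_log


def ztrace(z, fs=10.0):
    n = np.asarray(z, dtype=float).size
    return ProcessedTrace(time_s=np.arange(n) / fs, f0_au=np.ones(n),
                          pct_dff=np.asarray(z, float), z=np.asarray(z, float),
                          fit_order=1, channel=Channel.SIGNAL,
                          stats=(0.0, 1.0), fs_hz=fs)


class TestTrialFilters:
    def test_no_rewards_gives_empty_list(self):
        log = make_log([(10, EventCode.TONE_ON), (20, EventCode.TONE_OFF)])
        assert filter_rewarded_trials(log) == []

    def test_retrieval_latency_rule_keeps_3_and_4p9_drops_6(self, rewarded_trial_log):
        trials = filter_rewarded_trials(rewarded_trial_log)
        assert [t.np_t for t in trials] == [12.0, 91.0]
        assert all(t.tone_t <= t.np_t <= t.rec_t for t in trials)

    def test_retained_pokes_within_tone_duration(self, rewarded_trial_log):
        for t in filter_rewarded_trials(rewarded_trial_log):
            assert t.np_t - t.tone_t <= 10.0

    def test_single_incorrect_poke_kept(self):
        log = make_log([(30, EventCode.NP_INCORRECT)])
        assert list(filter_incorrect_events(log)) == [30.0]

    @pytest.mark.parametrize("times,expected", [
        ([10, 12, 20], [10, 20]),
        ([10, 14.9, 20], [10, 20]),   # 4.9 s gap: excluded at the 5 s bound
        ([10, 15.0, 20.0], [10, 15, 20]),
    ])
    def test_incorrect_refractory_rule(self, times, expected):
        log = make_log([(t, EventCode.NP_INCORRECT) for t in times])
        assert list(filter_incorrect_events(log)) == expected


class TestExtractPeriEvent:
    def test_fewer_than_three_trials_is_nothing_to_analyze(self):
        proc = ztrace(np.zeros(2000))
        assert extract_peri_event(proc, np.array([50.0, 100.0])) is None

    def test_index_arithmetic_half_open_window(self):
        z = np.arange(2000.0)
        proc = ztrace(z, fs=10.0)
        m = extract_peri_event(proc, np.array([100.0, 100.0, 100.0]))
        assert m.values.shape == (3, 150)
        np.testing.assert_array_equal(m.values[0], z[950:1100])
        assert m.bin_time_s[0] == -5.0
        assert m.bin_time_s[-1] == pytest.approx(10.0 - 0.1)

    def test_edge_trials_dropped_with_warning(self):
        proc = ztrace(np.zeros(2000))
        with pytest.warns(UserWarning, match="dropped"):
            m = extract_peri_event(proc, np.array([2.0, 100.0, 110.0, 120.0]))
        assert m.n_trials == 3

    def test_constant_trace_rows_constant(self):
        proc = ztrace(np.full(2000, 1.5))
        m = extract_peri_event(proc, np.array([60.0, 80.0, 100.0]))
        np.testing.assert_array_equal(m.values, 1.5)


LAYOUT = SegmentLayout()


class TestWarpTrial:
    def test_full_budget_trial_has_no_missing_bins(self):
        proc = ztrace(np.arange(2000.0))
        row = warp_trial(proc, 50.0, 54.0, 55.0, LAYOUT)
        assert row.size == LAYOUT.n_bins(10.0)
        assert not np.isnan(row).any()
        # full-budget segments are copied verbatim (mean-preserving)
        np.testing.assert_array_equal(row, proc.z[450:600])

    def test_two_second_latency_split_leaves_center_blank(self):
        proc = ztrace(np.arange(2000.0))
        row = warp_trial(proc, 50.0, 52.0, 53.0, LAYOUT)
        t2n = row[50:90]  # 4 s budget at fs 10
        np.testing.assert_array_equal(t2n[:10], proc.z[500:510])
        np.testing.assert_array_equal(t2n[30:], proc.z[510:520])
        assert np.isnan(t2n[10:30]).all()

    def test_odd_sample_count_extra_goes_to_leading_anchor(self):
        proc = ztrace(np.arange(2000.0))
        row = warp_trial(proc, 50.0, 51.5, 52.5, LAYOUT)  # 15 samples in 40
        t2n = row[50:90]
        assert np.isfinite(t2n[:8]).all() and np.isfinite(t2n[-7:]).all()
        assert np.isnan(t2n[8:-7]).all()

    def test_over_budget_latency_center_cropped(self):
        proc = ztrace(np.arange(2000.0))
        row = warp_trial(proc, 50.0, 56.0, 56.5, LAYOUT)  # 6 s > 4 s budget
        t2n = row[50:90]
        assert not np.isnan(t2n).any()
        np.testing.assert_array_equal(t2n[:20], proc.z[500:520])
        np.testing.assert_array_equal(t2n[20:], proc.z[540:560])

    def test_anchor_order_enforced(self):
        proc = ztrace(np.zeros(2000))
        with pytest.raises(AlignmentError):
            warp_trial(proc, 50.0, 49.0, 52.0, LAYOUT)

    def test_layout_geometry_is_data_independent(self):
        for fs in (10.0, 120.0):
            b = LAYOUT.boundaries(fs)
            assert b == (0, int(5 * fs), int(9 * fs), int(10 * fs), int(15 * fs))


class TestDailyHeatmap:
    def test_identical_trials_row_equals_single_trial(self):
        proc = ztrace(np.sin(np.arange(2000.0) / 50))
        trials = [Trial(50.0, 54.0, 55.0)] * 3
        hm = build_daily_heatmap([(1, proc, trials)], LAYOUT)
        np.testing.assert_allclose(
            hm.rows[0], warp_trial(proc, 50.0, 54.0, 55.0, LAYOUT), atol=1e-12)

    def test_day_with_two_trials_is_skipped_not_blanked(self):
        proc = ztrace(np.zeros(2000))
        hm = build_daily_heatmap(
            [(1, proc, [Trial(50.0, 52.0, 53.0)] * 2),
             (2, proc, [Trial(50.0, 52.0, 53.0)] * 3)], LAYOUT)
        assert hm.day_labels == [2]
        assert hm.rows.shape[0] == 1

    def test_binwise_mean_ignores_missing_entries(self):
        proc = ztrace(np.arange(2000.0))
        trials = [Trial(50.0, 52.0, 53.0), Trial(80.0, 84.0, 85.0),
                  Trial(120.0, 123.0, 124.0)]
        hm = build_daily_heatmap([(1, proc, trials)], LAYOUT)
        rows = np.array([warp_trial(proc, t.tone_t, t.np_t, t.rec_t, LAYOUT)
                         for t in trials])
        expected = np.nanmean(rows, axis=0)  # hand-averaging oracle
        np.testing.assert_allclose(hm.rows[0], expected)
        assert (hm.missing_mask[0] == np.isnan(expected)).all()


def _summaries(rewards, phase=Phase.TRAINING, start=1):
    return [SessionSummary(day=start + i, phase=phase, rewards=r,
                           correct_np=r, incorrect_np=0, inactive_np=0,
                           timeouts=0) for i, r in enumerate(rewards)]


class TestKeyDays:
    def test_milestone_rules_on_training_rewards(self):
        s = _summaries([4, 12, 8, 22, 25])
        keys = select_key_days(s)
        assert keys["first_10_rewards"] == 2
        assert keys["acquisition"] == 4

    def test_unreached_milestones_absent(self):
        keys = select_key_days(_summaries([4, 6, 8]))
        assert "first_10_rewards" not in keys
        assert "acquisition" not in keys

    def test_acquisition_milestone_matches_behavior_module(self):
        s = (_summaries([30, 28], phase=Phase.PRE_TRAINING)
             + _summaries([25, 18, 21, 22], start=3))
        assert select_key_days(s)["acquisition"] == detect_acquisition(s)
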