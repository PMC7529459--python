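"""Percentile bootstrap, consecutive-run masking, downsampling rules."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cuephot.align import PeriEventMatrix
from cuephot.bootstrap import (BootstrapLevel, BootstrapParams,
                               InsufficientTrialsError, bootstrap_ci,
                               downsample_trials, significance_mask)
from cuephot.events import EventCode


def matrix(values, fs=10.0):
    v = np.atleast_2d(np.asarray(values, dtype=float))
    return PeriEventMatrix(values=v,
                           bin_time_s=np.arange(v.shape[1]) / fs,
                           event_times_s=np.zeros(v.shape[0]),
                           anchor=EventCode.NP_CORRECT, fs_hz=fs)


def enumerate_percentiles(col, level=0.99):
    """Exhaustive resample-mean distribution for one bin (oracle)."""
    n = len(col)
    means = [np.mean([col[i] for i in draw])
             for draw in itertools.product(range(n), repeat=n)]
    a = (1 - level) / 2
    return np.quantile(means, [a, 1 - a])


class TestBootstrapCI:
    def test_identical_rows_degenerate_interval_all_significant(self):
        m = matrix(np.full((4, 20), 2.5))
        res = bootstrap_ci(m, BootstrapParams(n_boot=500, seed=0))
        np.testing.assert_array_equal(res.ci_low, 2.5)
        np.testing.assert_array_equal(res.ci_high, 2.5)
        assert res.sig_mask.all()

    def test_three_trial_single_bin_matches_enumeration_oracle(self):
        col = [0.0, 0.0, 3.0]
        lo_e, hi_e = enumerate_percentiles(col)
        m = matrix(np.array(col).reshape(3, 1))
        res = bootstrap_ci(m, BootstrapParams(n_boot=100_000, seed=1))
        # agreement within one enumeration quantile step (spacing 1.0 here)
        assert abs(res.ci_low[0] - lo_e) <= 1.0
        assert abs(res.ci_high[0] - hi_e) <= 1.0

    @pytest.mark.parametrize("rows,bins", [(3, 2), (4, 1)])
    def test_small_matrices_match_exhaustive_enumeration(self, rows, bins):
        rng = np.random.default_rng(rows * 10 + bins)
        x = rng.normal(0, 1, (rows, bins))
        res = bootstrap_ci(matrix(x), BootstrapParams(n_boot=100_000, seed=2))
        for b in range(bins):
            n = rows
            means = sorted(np.mean([x[list(draw), b]])
                           for draw in itertools.product(range(n), repeat=n))
            step = max(np.diff(means)) if len(means) > 1 else 0.0
            lo_e, hi_e = np.quantile(means, [0.005, 0.995])
            assert abs(res.ci_low[b] - lo_e) <= step + 1e-12
            assert abs(res.ci_high[b] - hi_e) <= step + 1e-12

    def test_same_seed_bit_identical(self):
        x = np.random.default_rng(3).normal(size=(8, 30))
        p = BootstrapParams(n_boot=2000, seed=9)
        a = bootstrap_ci(matrix(x), p)
        b = bootstrap_ci(matrix(x), p)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        np.testing.assert_array_equal(a.ci_high, b.ci_high)
        np.testing.assert_array_equal(a.sig_mask, b.sig_mask)

    def test_fewer_than_three_rows_rejected(self):
        with pytest.raises(InsufficientTrialsError):
            bootstrap_ci(matrix(np.zeros((2, 5))), BootstrapParams(n_boot=10))

    def test_bins_with_under_three_contributions_not_analyzable(self):
        x = np.random.default_rng(4).normal(5, 0.1, (5, 4))
        x[2:, 0] = np.nan  # only 2 finite rows in bin 0
        res = bootstrap_ci(matrix(x), BootstrapParams(n_boot=1000, seed=0))
        assert not res.analyzable[0] and res.analyzable[1:].all()
        assert np.isnan(res.ci_low[0]) and not res.sig_mask[0]

    def test_widening_ci_level_never_adds_significant_bins(self):
        x = np.random.default_rng(5).normal(0.4, 1.0, (10, 40))
        lo = bootstrap_ci(matrix(x), BootstrapParams(n_boot=4000, ci_level=0.9,
                                                     seed=7))
        hi = bootstrap_ci(matrix(x), BootstrapParams(n_boot=4000, ci_level=0.99,
                                                     seed=7))
        assert not np.any(hi.sig_mask & ~lo.sig_mask)

    def test_mouse_level_ci_from_averages_mean_from_pooled_trials(self):
        mouse_avgs = np.random.default_rng(6).normal(1, 0.2, (4, 10))
        pooled = np.random.default_rng(7).normal(1.5, 0.2, (40, 10))
        p = BootstrapParams(n_boot=1000, seed=1, level=BootstrapLevel.MOUSE)
        a = bootstrap_ci(matrix(mouse_avgs), p)
        b = bootstrap_ci(matrix(mouse_avgs), p, pooled_trials=pooled)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)   # CI: mouse level
        np.testing.assert_allclose(b.mean, pooled.mean(axis=0))  # line: pooled


class TestSignificanceMask:
    def test_ci_spanning_zero_never_significant(self):
        mask = significance_mask(np.full(50, -1.0), np.full(50, 1.0), 10, 0.5)
        assert not mask.any()

    def test_run_length_threshold_at_ceil_boundary(self):
        lo = np.zeros(20) - 1.0
        hi = np.ones(20)
        lo[3:7] = 0.1    # 4 bins = 0.4 s at fs 10: erased
        lo[10:15] = 0.1  # 5 bins = 0.5 s: retained
        mask = significance_mask(lo, hi, fs=10, consec_s=0.5)
        assert not mask[3:7].any()
        assert mask[10:15].all()

    def test_negative_going_interval_retained(self):
        # a sustained dip (upper bound below zero) counts as significant
        lo = np.full(20, -2.0)
        hi = np.full(20, 1.0)
        hi[5:12] = -0.1
        mask = significance_mask(lo, hi, fs=10, consec_s=0.5)
        assert mask[5:12].all() and mask.sum() == 7


class TestDownsampling:
    @pytest.mark.parametrize("n_other,primary,kept", [
        (58, 24, 24),   # joint correct/incorrect plot
        (141, 44, 44),
        (15, 24, 15),   # nothing to downsample
    ])
    def test_matching_rule(self, n_other, primary, kept, rng):
        out = downsample_trials(primary, np.arange(n_other), rng=rng)
        assert out.size == kept
        assert np.all(np.diff(out) > 0)  # order preserved, no repeats

    def test_daily_cap_of_20(self, rng):
        out = downsample_trials(None, np.arange(33), cap=20, rng=rng)
        assert out.size == 20

    def test_empty_input_rejected(self, rng):
        with pytest.raises(ValueError):
            downsample_trials(5, np.array([]), rng=rng)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**20))
def test_mask_runs_never_shorter_than_threshold(seed):
    rng = np.random.default_rng(seed)
    lo = rng.normal(0, 1, 60)
    hi = lo + np.abs(rng.normal(0, 1, 60))
    mask = significance_mask(lo, hi, fs=10, consec_s=0.5)
    runs = np.diff(np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0])))
    on_lengths = runs[::2] if mask.any() else []
    assert all(r >= 5 for r in on_lengths)
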