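import numpy as np
import pytest

from hrvdvc import (PhysioBounds, RRSeries, check_consistency, detect_gaps,
                    fill_gap, fit_local_gaussian, impute_dvc)
from hrvdvc.dvc_imputation import GapInfeasibleError, GapSpec, GaussianParams


def series_with_gap(pre, span, rr_end, post=(), t0=0.0):
    """Consistent series, then a gap of ``span``, then a consistent tail."""
    pre = list(pre)
    ts = list(t0 + np.cumsum(pre))
    rr = list(pre)
    t_end = ts[-1] + span
    for k, v in enumerate([rr_end, *post]):
        ts.append(t_end + sum(post[:k]))
        rr.append(v)
    return RRSeries(np.asarray(ts), np.asarray(rr))


class TestDetectGaps:
    def test_consistent_series_has_no_gaps(self, make_rr, bounds):
        assert detect_gaps(make_rr([0.8] * 5), bounds) == []

    def test_single_gap_fields(self, bounds):
        s = RRSeries(timestamps=[1.0, 1.8, 6.0], intervals=[1.0, 0.8, 0.8])
        gaps = detect_gaps(s, bounds)
        assert len(gaps) == 1
        g = gaps[0]
        assert (g.t_start, g.t_end, g.rr_end) == (1.8, 6.0, 0.8)
        assert g.span == pytest.approx(4.2)

    def test_two_gaps_in_time_order(self, bounds):
        s = series_with_gap([0.8, 0.8], 3.0, 0.8, post=[0.8])
        s2 = RRSeries(np.append(s.timestamps, s.timestamps[-1] + 2.0),
                      np.append(s.intervals, 0.8))
        gaps = detect_gaps(s2, bounds)
        assert len(gaps) == 2
        assert gaps[0].t_start < gaps[1].t_start


class TestFitLocalGaussian:
    def test_constant_history(self, bounds):
        s = series_with_gap([0.8] * 10, 4.0, 0.8)
        params = fit_local_gaussian(s, detect_gaps(s, bounds)[0], bounds)
        assert params.mu == pytest.approx(0.8)
        assert params.sigma == pytest.approx(0.0)
        assert params.n_source == 10

    def test_two_point_history_sample_sd(self, bounds):
        s = series_with_gap([0.7, 0.9], 4.0, 0.8)
        params = fit_local_gaussian(s, detect_gaps(s, bounds)[0], bounds)
        assert params.mu == pytest.approx(0.8)
        assert params.sigma == pytest.approx(0.2 / np.sqrt(2))
        assert params.n_source == 2

    def test_lookback_limits_history(self):
        b = PhysioBounds(lookback=3)
        s = series_with_gap([0.5] * 5 + [0.8] * 3, 4.0, 0.8, t0=0.0)
        params = fit_local_gaussian(s, detect_gaps(s, b)[0], b)
        assert params.mu == pytest.approx(0.8)
        assert params.n_source == 3


class TestFillGap:
    def test_residual_below_rr_max_closes_immediately(self, bounds):
        # span 2.2 with rr_end 1.1 leaves 1.1 s for a single closing beat
        s = series_with_gap([0.8] * 10, 2.2, 1.1)
        gap = detect_gaps(s, bounds)[0]
        params = fit_local_gaussian(s, gap, bounds)
        out = fill_gap(s, gap, params, bounds, rng_seed=0)
        assert len(out) == len(s) + 1
        inserted = out.intervals[10]
        assert inserted == pytest.approx(2.2 - 1.1)
        assert check_consistency(out) == []

    def test_zero_sigma_tiles_with_mean(self, bounds):
        s = series_with_gap([0.8] * 10, 4.0, 0.8)
        gap = detect_gaps(s, bounds)[0]
        params = GaussianParams(mu=0.8, sigma=0.0, n_source=10)
        out = fill_gap(s, gap, params, bounds, rng_seed=1)
        ins = out.intervals[10:len(out) - 1]
        # all inserted intervals are 0.8 except the closing residual
        np.testing.assert_allclose(ins[:-1], 0.8)
        assert check_consistency(out) == []
        assert abs(out.timestamps[len(out) - 1] - gap.t_end) < 1e-9

    def test_fill_is_deterministic_in_seed(self, bounds):
        s = series_with_gap([0.75, 0.8, 0.85] * 3, 6.3, 0.8)
        gap = detect_gaps(s, bounds)[0]
        params = fit_local_gaussian(s, gap, bounds)
        a = fill_gap(s, gap, params, bounds, rng_seed=42)
        b = fill_gap(s, gap, params, bounds, rng_seed=42)
        c = fill_gap(s, gap, params, bounds, rng_seed=43)
        np.testing.assert_array_equal(a.intervals, b.intervals)
        assert len(c) != len(a) or not np.array_equal(a.intervals, c.intervals)

    def test_inserted_intervals_respect_bounds(self, bounds):
        s = series_with_gap([0.7, 0.9] * 5, 4.2, 0.8)
        gap = detect_gaps(s, bounds)[0]
        out = fill_gap(s, gap, GaussianParams(0.8, 0.05, 10), bounds, rng_seed=7)
        ins = out.intervals[10:len(out) - 1]
        assert ((ins >= bounds.rr_min) & (ins <= bounds.rr_max)).all()
        assert check_consistency(out) == []

    def test_infeasible_sliver_raises(self, bounds):
        # span 1.35 with rr_end 1.2 leaves a 0.15 s residual: no in-bounds
        # interval can tile it
        s = series_with_gap([0.8] * 5, 1.35, 1.2)
        gap = detect_gaps(s, bounds)[0]
        with pytest.raises(GapInfeasibleError):
            fill_gap(s, gap, GaussianParams(0.8, 0.05, 5), bounds, rng_seed=0)

    def test_termination_over_random_gaps(self, bounds):
        rng = np.random.default_rng(5)
        for _ in range(300):
            span = rng.uniform(1.31, 60.0)
            mu = rng.uniform(0.4, 1.2)
            sigma = rng.uniform(0.0, 0.3)
            rr_end = rng.uniform(0.3, 1.3)
            if span - rr_end <= bounds.rr_min + 1e-6:
                continue
            s = series_with_gap([0.7, 0.9] * 5, span, rr_end)
            gap = detect_gaps(s, bounds)[0]
            out = fill_gap(s, gap, GaussianParams(mu, sigma, 10), bounds,
                           rng_seed=int(rng.integers(2**31)))
            assert check_consistency(out) == []
            ins = out.intervals[10:len(out) - 1]
            assert ((ins >= bounds.rr_min) & (ins <= bounds.rr_max)).all()


class TestImputeDvc:
    def test_gap_free_series_unchanged(self, make_rr, bounds):
        s = make_rr([0.8] * 20)
        out, log = impute_dvc(s, bounds, rng_seed=0)
        np.testing.assert_array_equal(out.intervals, s.intervals)
        assert log == []

    def test_two_gaps_both_filled(self, bounds):
        s = series_with_gap([0.8] * 12, 3.0, 0.8, post=[0.8] * 5)
        ts = np.append(s.timestamps, s.timestamps[-1] + 2.5)
        rr = np.append(s.intervals, 0.8)
        s2 = RRSeries(ts, rr)
        out, log = impute_dvc(s2, bounds, rng_seed=3)
        assert check_consistency(out) == []
        assert detect_gaps(out, bounds) == []
        assert len(log) == 2 and all(e["filled"] for e in log)

    def test_infeasible_sliver_consumes_pre_gap_beat(self, bounds):
        s = series_with_gap([0.8] * 5, 1.35, 1.2)
        out, log = impute_dvc(s, bounds, rng_seed=0)
        assert check_consistency(out) == []
        assert detect_gaps(out, bounds) == []
        assert log[0]["dropped_pre_gap_beats"] >= 1

    def test_beat_count_preserved_after_heavy_deletion(self, bounds):
        from hrvdvc import degrade, filter_ectopics, simulate_preset
        s = simulate_preset("relax", 600, seed=9)
        deg, _ = degrade(s, 20, 0, seed=4)
        filt, _ = filter_ectopics(deg, bounds)
        out, _ = impute_dvc(filt, bounds, rng_seed=1)
        assert abs(len(out) - len(s)) <= 0.1 * len(s)

    def test_distribution_recovery_long_gap(self, bounds):
        # mild truncation: pre-gap variability puts the budget near 0.25
        s = series_with_gap([0.7, 0.9] * 10, 240.37, 0.8)
        gap = detect_gaps(s, bounds)[0]
        params = GaussianParams(mu=0.8, sigma=0.05, n_source=20)
        means = []
        for seed in range(10):
            out = fill_gap(s, gap, params, bounds, rng_seed=seed)
            ins = out.intervals[20:len(out) - 1]
            assert len(ins) >= 200
            means.append(ins.mean())
        n = len(ins)
        assert abs(np.mean(means) - 0.8) <= 3 * 0.05 / np.sqrt(n)
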