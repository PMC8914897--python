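import numpy as np
import pytest

from hrvdvc import (RRSeries, engineer_features, features_table, pnn50,
                    poincare_sd, rmssd, sdnn, simulate_rr, sliding_windows,
                    spectral_powers)


class TestTimeDomain:
    def test_sdnn_constant_is_zero(self):
        assert sdnn([0.8, 0.8, 0.8]) == pytest.approx(0.0, abs=1e-9)

    def test_sdnn_two_points(self):
        # sample SD of {0.7, 0.9} = 0.1414... s
        assert sdnn([0.7, 0.9]) == pytest.approx(141.42, abs=0.01)

    def test_sdnn_order_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.5, 1.0, 50)
        assert sdnn(x) == pytest.approx(sdnn(np.sort(x)))

    def test_sdnn_undefined_below_two(self):
        assert np.isnan(sdnn([0.8]))

    @pytest.mark.parametrize("x,expected", [
        ([0.8, 0.8, 0.8], 0.0),
        ([0.8, 0.9], 100.0),
        ([0.8, 0.9, 0.8], 100.0),  # sqrt((0.01 + 0.01)/2) in ms
    ])
    def test_rmssd_hand_values(self, x, expected):
        assert rmssd(x) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("x,nn,pct", [
        ([0.8] * 5, 0, 0.0),
        ([0.8, 0.9, 0.8], 2, 100.0),
        ([0.80, 0.84, 0.80], 0, 0.0),
    ])
    def test_pnn50_counts_50ms_exceedances(self, x, nn, pct):
        got_nn, got_pct = pnn50(x)
        assert (got_nn, got_pct) == (nn, pct)

    def test_scaling_linearity(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.6, 1.0, 100)
        assert sdnn(2 * x) == pytest.approx(2 * sdnn(x))
        assert rmssd(2 * x) == pytest.approx(2 * rmssd(x))


class TestPoincare:
    def test_constant_series_degenerate(self):
        assert poincare_sd([0.8] * 10) == (0.0, 0.0)

    def test_sum_of_squares_identity(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.5, 1.1, 500)
        sd1, sd2 = poincare_sd(x)
        total = (sd1**2 + sd2**2) / 1e6
        assert total == pytest.approx(2 * np.var(x, ddof=1), rel=1e-9)

    def test_alternating_series_collapses_sd2(self):
        x = np.tile([0.6, 1.0], 200)
        sd1, sd2 = poincare_sd(x)
        assert sd1 > 100
        assert sd2 < 0.1 * sd1

    def test_iid_series_sd1_tracks_overall_sd(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.8, 0.05, 5000)
        sd1, sd2 = poincare_sd(x)
        assert sd1 == pytest.approx(np.std(x, ddof=1) * 1e3, rel=0.05)

    def test_rmssd_sd1_relationship(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.6, 1.0, 200)
        sd1, _ = poincare_sd(x)
        # RMSSD aggregates raw squared diffs; SD1 the centred ones:
        # sum d^2 = sum (d - dbar)^2 + (N-1) dbar^2
        n = len(x)
        dbar = float(np.mean(np.diff(x))) * 1e3
        lhs = rmssd(x) ** 2 * (n - 1)
        rhs = 2 * sd1**2 * (n - 2) + (n - 1) * dbar**2
        assert lhs == pytest.approx(rhs, rel=1e-9)


class TestSpectral:
    def test_pure_hf_tone_lands_in_hf_band(self):
        s = simulate_rr(300, mean_rr=0.8, sdnn_target=0.03, lf_amp=0.0,
                        hf_amp=0.03 * np.sqrt(2), hf_hz=0.25, seed=0)
        lf, hf, ratio = spectral_powers(s)
        assert hf / (lf + hf) >= 0.95
        assert ratio < 0.1

    def test_pure_lf_tone_lands_in_lf_band(self):
        s = simulate_rr(300, mean_rr=0.8, sdnn_target=0.03,
                        lf_amp=0.03 * np.sqrt(2), hf_amp=0.0, lf_hz=0.1, seed=0)
        lf, hf, ratio = spectral_powers(s)
        assert lf / (lf + hf) >= 0.95
        assert ratio > 10

    def test_constant_series_has_no_band_power(self):
        s = RRSeries.from_intervals([0.8] * 400)
        lf, hf, _ = spectral_powers(s)
        assert lf < 1e-6 and hf < 1e-6

    def test_short_window_undefined(self):
        s = RRSeries.from_intervals([0.8] * 50)  # 40 s
        lf, hf, ratio = spectral_powers(s)
        assert np.isnan(lf) and np.isnan(hf)

    def test_between_one_and_two_minutes_only_hf(self):
        s = RRSeries.from_intervals([0.8] * 120)  # 96 s
        lf, hf, _ = spectral_powers(s)
        assert np.isnan(lf) and not np.isnan(hf)


class TestWindows:
    @pytest.mark.parametrize("minutes,expected", [(15, 11), (5, 1), (4, 0)])
    def test_window_counts(self, minutes, expected):
        s = RRSeries.from_intervals([0.8] * int(minutes * 60 / 0.8))
        assert len(sliding_windows(s)) == expected

    def test_window_features_populated(self):
        s = simulate_rr(420, seed=5)
        wins = sliding_windows(s)
        assert len(wins) == 3
        for w in wins:
            assert w.n_beats > 300
            assert w.sdnn > 0 and w.rmssd > 0
            assert not np.isnan(w.lf_power)

    def test_features_table_columns(self):
        s = simulate_rr(320, seed=6)
        tab = features_table(s)
        assert list(tab.columns)[:2] == ["t0", "sdnn"]
        assert len(tab) == 1


class TestEngineerFeatures:
    def test_pairwise_expansion_count(self):
        s = simulate_rr(400, seed=7)
        base = features_table(s)
        cols = ["rmssd", "sdnn", "lf_power", "hf_power"]
        out = engineer_features(base, columns=cols)
        added = set(out.columns) - set(base.columns)
        assert len(added) == 2 * 6  # 2 * C(4, 2)
        assert "rmssd_div_sdnn" in out.columns
        assert "rmssd_x_sdnn" in out.columns

    def test_full_base_set_expansion(self):
        s = simulate_rr(400, seed=8)
        out = engineer_features(features_table(s))
        # 9 base features -> 9 + 2 * C(9,2) = 81 feature columns
        added = [c for c in out.columns if "_x_" in c or "_div_" in c]
        assert len(added) == 72

    def test_zero_denominator_yields_nan(self):
        import pandas as pd
        base = pd.DataFrame({"rmssd": [1.0], "sdnn": [0.0]})
        out = engineer_features(base, columns=["rmssd", "sdnn"])
        assert np.isnan(out["rmssd_div_sdnn"].iloc[0])
        assert not np.isinf(out.to_numpy(dtype=float)).any()
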