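import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sys

from spitrain import (
    compare_durations,
    compute_correlogram,
    compute_ipis,
    count_runs,
    extract_features,
    permutation_chance_band,
    scramble_ipis,
    serial_correlation,
    simulate_ipis,
    two_state_memory_config,
)
from spitrain.ipi_stats import IPISequence
from spitrain.pulse_io import PulseTrain
from spitrain.serial_correlation import (
    SerialCorrelogram,
    average_correlograms,
    sc_duration,
)


def naive_sc(x, max_lag):
    """Literal double-loop transcription of the lagged-product definition."""
    n = len(x)
    mean = sum(x) / n
    var = sum(v * v for v in x) / n - mean * mean
    out = []
    for i in range(max_lag + 1):
        acc = 0.0
        for k in range(n - i):
            acc += x[k] * x[k + i]
        out.append((acc / (n - i) - mean * mean) / var)
    return np.array(out)


class TestSerialCorrelation:
    def test_lag_zero_is_exactly_one(self, rng):
        seq = IPISequence(rng.gamma(3.0, 20.0, 300))
        assert serial_correlation(seq, 10)[0] == 1.0

    def test_alternating_sequence(self):
        seq = IPISequence(np.tile([10.0, 20.0], 100))
        sc = serial_correlation(seq, 2)
        assert sc[1] == pytest.approx(-1.0, abs=0.02)
        assert sc[2] == pytest.approx(1.0, abs=0.02)

    def test_matches_naive_double_loop(self, rng):
        for _ in range(5):
            n = int(rng.integers(50, 500))
            x = rng.gamma(4.0, 25.0, n)
            sc = serial_correlation(IPISequence(x), min(100, n - 2))
            np.testing.assert_allclose(sc, naive_sc(list(x), min(100, n - 2)),
                                       atol=1e-10, rtol=0)

    def test_fft_path_matches_direct_path(self, rng, monkeypatch):
        x = rng.gamma(4.0, 25.0, 3000)
        via_fft = serial_correlation(IPISequence(x), 150)
        scmod = sys.modules["spitrain.serial_correlation"]
        monkeypatch.setattr(scmod, "_FFT_THRESHOLD", 10**9)
        via_dot = serial_correlation(IPISequence(x), 150)
        np.testing.assert_allclose(via_fft, via_dot, atol=1e-9, rtol=0)

    def test_constant_sequence_is_degenerate(self):
        with pytest.raises(ValueError, match="variance"):
            serial_correlation(IPISequence([5.0] * 100), 3)

    def test_max_lag_too_large_errors(self):
        with pytest.raises(ValueError, match="too short"):
            serial_correlation(IPISequence([1.0, 2.0, 3.0]), 5)


class TestScramble:
    @given(st.lists(st.floats(0.5, 500.0), min_size=2, max_size=50),
           st.integers(0, 2**31 - 1))
    def test_preserves_interval_multiset(self, intervals, seed):
        seq = IPISequence(intervals)
        out = scramble_ipis(seq, seed=seed)
        np.testing.assert_allclose(np.sort(out.intervals), np.sort(seq.intervals))

    def test_deterministic_per_seed(self, rng):
        seq = IPISequence(rng.gamma(3.0, 20.0, 200))
        a = scramble_ipis(seq, seed=7)
        b = scramble_ipis(seq, seed=7)
        c = scramble_ipis(seq, seed=8)
        np.testing.assert_array_equal(a.intervals, b.intervals)
        assert not np.array_equal(a.intervals, c.intervals)

    def test_order_free_features_invariant_under_scrambling(self):
        cfg = two_state_memory_config(dwell_intervals=30.0)
        intervals = simulate_ipis(cfg, 2000, seed=5)
        times = np.concatenate([[0.0], np.cumsum(intervals)]) / 1000.0
        train = PulseTrain(times, duration_s=float(times[-1]))
        scrambled = scramble_ipis(compute_ipis(train), seed=1)
        st_times = np.concatenate([[0.0], np.cumsum(scrambled.intervals)]) / 1000.0
        strain = PulseTrain(st_times, duration_s=float(st_times[-1]))
        f0 = extract_features(train, window_length_s=None)
        f1 = extract_features(strain, window_length_s=None)
        assert f0.total_eods == f1.total_eods
        assert f0.mode_ipi_ms == f1.mode_ipi_ms
        assert f0.range_high_ms == pytest.approx(f1.range_high_ms)
        assert f0.range_low_ms == pytest.approx(f1.range_low_ms)
        # temporal order is the one thing scrambling destroys
        assert f0.n_runs != f1.n_runs


class TestChanceBand:
    def test_white_sequence_matches_normal_theory(self, rng):
        n = 2000
        seq = IPISequence(rng.gamma(4.0, 20.0, n))
        upper, lower = permutation_chance_band(seq, 150, seed=3)
        from scipy.stats import norm
        theory = norm.ppf(0.99) / np.sqrt(n)
        assert upper == pytest.approx(theory, rel=0.20)
        assert lower == pytest.approx(-theory, rel=0.20)
        assert lower < upper

    def test_alpha_half_limit_collapses_to_permutation_mean(self, rng):
        seq = IPISequence(rng.gamma(4.0, 20.0, 500))
        upper, lower = permutation_chance_band(seq, 50, alpha=0.5, seed=3)
        assert abs(upper) < 0.01
        assert upper == lower  # z-score at alpha = 0.5 is 0: both collapse to the mean

    def test_deterministic_per_seed(self, rng):
        seq = IPISequence(rng.gamma(4.0, 20.0, 400))
        assert permutation_chance_band(seq, 30, seed=9) == \
            permutation_chance_band(seq, 30, seed=9)

    @pytest.mark.parametrize("method, pooling",
                             [("percentile", "per_lag"), ("normal", "pooled")])
    def test_alternative_band_constructions_agree_roughly(self, rng, method, pooling):
        seq = IPISequence(rng.gamma(4.0, 20.0, 1000))
        base, _ = permutation_chance_band(seq, 100, seed=4)
        alt, _ = permutation_chance_band(seq, 100, seed=4, method=method,
                                         pooling=pooling)
        assert alt == pytest.approx(base, rel=0.35)

    def test_too_few_permutations_error(self, rng):
        seq = IPISequence(rng.gamma(4.0, 20.0, 100))
        with pytest.raises(ValueError):
            permutation_chance_band(seq, 10, n_permutations=1)


class TestScDuration:
    def _manual_correlogram(self, drop_lag, max_lag=100):
        sc = np.ones(max_lag + 1)
        sc[drop_lag:] = 0.0
        return SerialCorrelogram(
            lags=np.arange(max_lag + 1), sc=sc, chance_upper=0.05,
            chance_lower=-0.05, n_permutations=250, alpha=0.01,
            median_ipi_ms=20.0,
        )

    def test_direct_product(self):
        cg = self._manual_correlogram(drop_lag=50)
        seq = IPISequence([20.0] * 5 + [10.0, 30.0])  # median 20 ms
        assert sc_duration(cg, seq) == pytest.approx(50 * 20.0)
        assert cg.first_subthreshold_lag == 50
        assert not cg.censored

    def test_censoring_when_sc_never_drops(self):
        cg = self._manual_correlogram(drop_lag=101)  # never below band
        seq = IPISequence([20.0] * 7)
        assert sc_duration(cg, seq) == pytest.approx(100 * 20.0)
        assert cg.censored

    def test_scrambled_sequence_decorrelates_at_lag_one(self):
        cfg = two_state_memory_config(dwell_intervals=40.0)
        hits = 0
        for s in range(10):
            seq = IPISequence(simulate_ipis(cfg, 2000, seed=s))
            scr = scramble_ipis(seq, seed=100 + s)
            cg = compute_correlogram(scr, max_lag=150, seed=200 + s)
            hits += cg.first_subthreshold_lag == 1
        assert hits >= 8

    def test_memory_train_exceeds_chance_at_lag_one(self):
        cfg = two_state_memory_config(dwell_intervals=40.0)
        seq = IPISequence(simulate_ipis(cfg, 3000, seed=1))
        cg = compute_correlogram(seq, max_lag=150, seed=2)
        assert cg.sc[1] > cg.chance_upper
        assert cg.duration_ms > cg.median_ipi_ms


class TestAverageAndCompare:
    def _cg(self, sc_values):
        sc = np.concatenate([[1.0], sc_values])
        return SerialCorrelogram(
            lags=np.arange(sc.size), sc=sc, chance_upper=0.05, chance_lower=-0.05,
            n_permutations=250, alpha=0.01, median_ipi_ms=10.0,
        )

    def test_identical_correlograms(self):
        cg = self._cg(np.array([0.5, 0.2, 0.1]))
        pop = average_correlograms([cg, cg])
        np.testing.assert_allclose(pop.mean, cg.sc)
        np.testing.assert_allclose(pop.std, 0.0)

    def test_mirrored_pair_averages_to_zero(self):
        a = self._cg(np.array([0.4, -0.3]))
        b = self._cg(np.array([-0.4, 0.3]))
        pop = average_correlograms([a, b])
        np.testing.assert_allclose(pop.mean[1:], 0.0, atol=1e-15)

    def test_mismatched_lag_grids_error(self):
        with pytest.raises(ValueError, match="lag"):
            average_correlograms([self._cg(np.array([0.1])),
                                  self._cg(np.array([0.1, 0.2]))])

    def test_renewal_replicates_stay_inside_band(self, rng):
        cgs = []
        for s in range(12):
            seq = IPISequence(np.random.default_rng(s).gamma(4.0, 20.0, 2000))
            cgs.append(compute_correlogram(seq, max_lag=100, seed=50 + s))
        pop = average_correlograms(cgs)
        band = np.mean([cg.chance_upper for cg in cgs])
        assert np.all(pop.mean[1:] < band)

    def test_compare_durations_identical_groups(self):
        out = compare_durations({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert out["pvalue"] == pytest.approx(1.0)

    def test_compare_durations_disjoint_support(self):
        out = compare_durations({"a": [1.0, 2.0, 3.0], "b": [100.0, 101.0, 102.0]})
        assert out["pvalue"] < 0.05
        assert out["medians"]["b"] > out["medians"]["a"]

    def test_compare_durations_group_size_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_durations({"a": [1.0], "b": [1.0, 2.0]})

    def test_short_vs_long_memory_cohorts(self):
        durations = {}
        for label, dwell in [("short", 10.0), ("long", 60.0)]:
            cfg = two_state_memory_config(dwell_intervals=dwell)
            durs = []
            for s in range(12):
                seq = IPISequence(simulate_ipis(cfg, 2500, seed=s))
                durs.append(compute_correlogram(seq, max_lag=200, seed=300 + s).duration_ms)
            durations[label] = durs
        out = compare_durations(durations)
        assert out["medians"]["short"] < out["medians"]["long"]
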