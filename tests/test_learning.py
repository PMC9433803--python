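import numpy as np
import pytest

from meaburst.core import ElectrodeGrid, SpikeTrainSet, active_electrodes
from meaburst.errors import ConfigError
from meaburst.learning import (
    build_trial_response_table,
    entropy_ratio,
    fit_trial_trend,
    isi_entropy,
    localize,
    response_flag,
    response_time,
)
from meaburst.protocol import ResponseWindow, StimulusLog

from oracles import entropy_brute


class TestResponseFlag:
    def test_above_mean(self):
        assert response_flag(5, 2.0) is True

    def test_equal_mean_is_strict(self):
        assert response_flag(2, 2.0) is False


class TestResponseTime:
    def test_mean_of_first_three(self):
        assert response_time([25.0, 40.0, 70.0, 90.0]) == pytest.approx(45.0)

    def test_single_spike(self):
        assert response_time([120.0]) == pytest.approx(120.0)

    def test_empty_undefined(self):
        assert response_time([]) is None


class TestTrendFit:
    def test_perfect_line(self):
        fit = fit_trial_trend(np.arange(1.0, 33.0), min_defined_trials=8)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.p == pytest.approx(0.0, abs=1e-12)

    def test_constant_series(self):
        fit = fit_trial_trend(np.full(32, 0.5), min_defined_trials=8)
        assert fit.slope == pytest.approx(0.0)
        assert fit.r == pytest.approx(0.0)

    def test_nan_skipped_and_min_trials(self):
        vals = np.full(32, np.nan)
        vals[:7] = 1.0
        assert fit_trial_trend(vals, min_defined_trials=8) is None
        vals[7] = 1.0
        assert fit_trial_trend(vals, min_defined_trials=8) is not None

    def test_planted_slope_recovery_noise_free(self):
        slope = 0.7 / 31.0
        y = 0.2 + slope * np.arange(32.0)
        fit = fit_trial_trend(y)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_scipy_linregress(self, rng):
        from scipy import stats

        y = rng.random(32)
        fit = fit_trial_trend(y)
        ref = stats.linregress(np.arange(1, 33), y)
        assert fit.slope == pytest.approx(ref.slope)
        assert fit.r == pytest.approx(ref.rvalue)
        assert fit.p == pytest.approx(ref.pvalue)


def synthetic_table(grid, rs_slopes, rt_slopes, n_trials=32):
    """Build a minimal TrialResponseTable-like object directly via localize's
    input contract: craft rs and mean_rt matrices with planted slopes."""
    from meaburst.learning import TrialResponseTable

    E = len(rs_slopes)
    trials = np.arange(n_trials, dtype=float)
    rs = np.clip(0.3 + np.outer(rs_slopes, trials), 0, 1)
    rt = np.clip(100.0 + np.outer(rt_slopes, trials), 10, 200)
    S = n_trials
    return TrialResponseTable(
        electrodes=np.arange(E),
        counts=np.zeros((E, S), dtype=int),
        flags=np.zeros((E, S), dtype=bool),
        stim_rt=np.full((E, S), np.nan),
        network_mean=np.zeros(S),
        trial_of_stim=np.arange(S),
        n_trials=n_trials,
        rs=rs,
        mean_rt=rt,
    )


class TestLocalize:
    def test_flat_everything_empty_mask(self, small_grid):
        table = synthetic_table(small_grid, [0.0, 0.0], [0.0, 0.0])
        lmap = localize(table)
        assert lmap.learning_mask.sum() == 0

    def test_intersection_rule(self, small_grid):
        # e0: rising R/S + falling RT -> learning; e1: rising R/S + rising RT -> excluded
        table = synthetic_table(small_grid, [0.01, 0.01, -0.01], [-1.0, 1.0, -1.0])
        lmap = localize(table)
        assert lmap.learning_mask.tolist() == [True, False, False]
        assert lmap.rs_mask.tolist() == [True, True, False]
        assert lmap.rt_mask.tolist() == [True, False, True]

    def test_permutation_equivariance(self, small_grid, rng):
        rs = rng.normal(0, 0.01, 6)
        rt = rng.normal(0, 1.0, 6)
        base = localize(synthetic_table(small_grid, rs, rt)).learning_mask
        perm = rng.permutation(6)
        shuffled = localize(synthetic_table(small_grid, rs[perm], rt[perm])).learning_mask
        assert np.array_equal(base[perm], shuffled)


class TestTrialResponseTable:
    def test_planted_latencies_recovered(self, small_grid):
        # stimulus at 1000 ms; electrode 0 responds at +25,+40,+70; e1 silent
        s = SpikeTrainSet(
            spikes={0: np.array([1025.0, 1040.0, 1070.0]), 1: np.array([50.0])},
            duration=3000.0,
            grid=small_grid,
        )
        log = StimulusLog(events=[(1000.0, 0, 0, 0)])
        table = build_trial_response_table(s, log, ResponseWindow(), active_electrodes(s))
        i0 = list(table.electrodes).index(0)
        i1 = list(table.electrodes).index(1)
        assert table.counts[i0, 0] == 3
        assert table.stim_rt[i0, 0] == pytest.approx(45.0)
        assert table.counts[i1, 0] == 0
        assert np.isnan(table.stim_rt[i1, 0])
        # network mean = 1.5; only e0 exceeds it
        assert table.flags[i0, 0] and not table.flags[i1, 0]
        assert table.rs[i0, 0] == 1.0 and table.rs[i1, 0] == 0.0

    def test_rs_values_on_grid(self, small_grid, rng):
        # 10 stimuli -> R/S must be multiples of 0.1
        times = 1000.0 + np.arange(10) * 1000.0
        spikes = {}
        for e in range(4):
            resp = rng.random(10) < 0.5
            ts = [t + 30.0 for t, r in zip(times, resp) if r]
            if ts:
                spikes[e] = np.array(ts)
        spikes[5] = np.array([100.0])
        s = SpikeTrainSet(spikes=spikes, duration=20000.0, grid=small_grid)
        log = StimulusLog(events=[(t, 0, 0, i) for i, t in enumerate(times)])
        table = build_trial_response_table(s, log, ResponseWindow(), active_electrodes(s))
        assert np.allclose(np.round(table.rs * 10), table.rs * 10)
        assert np.all((table.rs >= 0) & (table.rs <= 1))
        defined = table.stim_rt[~np.isnan(table.stim_rt)]
        assert np.all((defined > 10.0) & (defined <= 200.0))


class TestEntropy:
    def test_uniform_four_bins(self):
        # ISIs uniformly over 4 distinct bins -> 2 bits
        spikes = np.cumsum([0.0, 5.0, 15.0, 25.0, 35.0])
        out = isi_entropy(spikes, bin_width=10.0, max_isi=1000.0)
        assert out.entropy == pytest.approx(2.0)

    def test_single_bin_zero_bits(self):
        spikes = np.arange(0.0, 50.0, 5.0)
        assert isi_entropy(spikes).entropy == pytest.approx(0.0)

    def test_half_quarter_quarter(self):
        # bin mass {0.5, 0.25, 0.25} -> 1.5 bits
        isis = [5.0, 5.0, 15.0, 25.0]
        spikes = np.concatenate([[0.0], np.cumsum(isis)])
        out = isi_entropy(spikes)
        assert out.entropy == pytest.approx(1.5)
        assert out.entropy == pytest.approx(entropy_brute(out.probs))

    def test_too_few_spikes_undefined(self):
        assert isi_entropy(np.array([1.0])) is None

    def test_probs_sum_to_one_and_bounded(self, rng):
        spikes = np.unique(rng.random(200) * 10_000.0)
        out = isi_entropy(spikes)
        assert out.probs.sum() == pytest.approx(1.0)
        assert 0.0 <= out.entropy <= np.log2(out.n_bins)

    def test_overflow_bin(self):
        spikes = np.array([0.0, 2000.0, 5000.0])  # both ISIs >= max_isi
        out = isi_entropy(spikes)
        assert out.entropy == pytest.approx(0.0)
        assert out.probs[-1] == pytest.approx(1.0)


class TestEntropyRatio:
    def test_all_learning_is_one(self):
        ent = {0: 1.0, 1: 2.0, 2: 0.5}
        assert entropy_ratio([0, 1, 2], ent) == pytest.approx(1.0)

    def test_empty_learning_is_zero(self):
        assert entropy_ratio([], {0: 1.0}) == pytest.approx(0.0)

    def test_planted_share(self):
        ent = {0: 3.0, 1: 1.0, 2: 1.0, 3: 1.0}
        assert entropy_ratio([0], ent) == pytest.approx(0.5)
        assert entropy_ratio([0], ent, mode="mean") == pytest.approx(3.0 / 1.5)

    def test_bad_mode(self):
        with pytest.raises(ConfigError):
            entropy_ratio([0], {0: 1.0}, mode="median")
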