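import dataclasses

import numpy as np
import pytest
from scipy import stats

from meaburst.core import ElectrodeGrid, active_electrodes
from meaburst.errors import ConfigError
from meaburst.io import write_spike_trains
from meaburst.protocol import StimulationProtocol
from meaburst.synthetic import (
    SimulationConfig,
    simulate_learning_phase,
    simulate_post_learning,
    simulate_spontaneous,
)

GRID = ElectrodeGrid(n_rows=16, n_cols=16)


class TestConfigValidation:
    def test_bad_probability(self):
        with pytest.raises(ConfigError):
            SimulationConfig(rs_start=1.5)

    def test_bad_rt_order(self):
        with pytest.raises(ConfigError):
            SimulationConfig(rt_start=40.0, rt_end=150.0)

    def test_bad_speed(self):
        with pytest.raises(ConfigError):
            SimulationConfig(propagation_speed=0.0)

    def test_bicuculline_scaling(self):
        base = SimulationConfig()
        bic = SimulationConfig(bicuculline_mode=True)
        assert bic.eff_burst_rate == pytest.approx(2 * base.eff_burst_rate)
        assert bic.eff_burst_len_range[1] == pytest.approx(1.5 * base.burst_len_range[1])
        assert bic.eff_participation == pytest.approx(min(1.0, 1.3 * base.participation_fraction))


class TestSpontaneous:
    def test_noise_free_latencies_exact(self):
        cfg = SimulationConfig(
            seed=5, duration=60_000.0, background_rate=0.0, latency_jitter_sd=0.0,
            burst_sites=((8, 8),), burst_rate=4.0,
        )
        res = simulate_spontaneous(cfg, GRID)
        assert res.bursts, "expected at least one burst"
        site = GRID.position(GRID.index(8, 8))
        for ann in res.bursts:
            for e in ann.electrodes:
                lat = res.spike_set.train(e)
                lat = lat[(lat >= ann.t0) & (lat < ann.t_end)]
                expected = np.hypot(*(GRID.position(e) - site)) / cfg.propagation_speed
                assert lat.size >= 1
                assert lat[0] == pytest.approx(ann.t0 + expected, abs=1e-6)

    def test_pure_poisson_counts(self):
        cfg = SimulationConfig(seed=7, duration=120_000.0, burst_rate=0.0, background_rate=0.5, burst_sites=((8, 8),))
        res = simulate_spontaneous(cfg, GRID)
        assert res.bursts == []
        lam = 0.5 * 120.0
        counts = [res.spike_set.n_spikes(e) for e in range(GRID.n_electrodes)]
        assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam) / np.sqrt(len(counts))
        for c in counts:
            assert abs(c - lam) < 5 * np.sqrt(lam)

    def test_burst_count_in_poisson_interval(self):
        cfg = SimulationConfig(seed=11, duration=300_000.0, burst_rate=4.0, background_rate=0.0, burst_sites=((8, 8),))
        res = simulate_spontaneous(cfg, GRID)
        # 5 min at 4/min -> ~20; refractory thinning keeps it near the
        # Poisson(20) 99% interval
        lo, hi = stats.poisson.ppf([0.005, 0.995], 20.0)
        assert lo <= len(res.bursts) <= hi

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=42, duration=30_000.0, burst_sites=((4, 4),))
        a = simulate_spontaneous(cfg, GRID)
        b = simulate_spontaneous(cfg, GRID)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_spike_trains(a.spike_set, pa)
        write_spike_trains(b.spike_set, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_annotations_respect_invariants(self):
        cfg = SimulationConfig(seed=2, duration=60_000.0, burst_sites=((4, 4), (12, 12)))
        res = simulate_spontaneous(cfg, GRID)
        for ann in res.bursts:
            assert 0 <= ann.t0 < cfg.duration
            assert ann.site_rc in cfg.burst_sites
            assert len(ann.electrodes) == round(cfg.participation_fraction * GRID.n_electrodes)

    def test_rate_validation(self):
        with pytest.raises(ConfigError):
            SimulationConfig(background_rate=-1.0)


class TestPostLearning:
    def test_hub_bursts_annotated_new_pattern(self):
        cfg = SimulationConfig(seed=9, duration=120_000.0, burst_sites=((2, 2),), background_rate=0.0)
        hub = GRID.index(12, 12)
        res = simulate_post_learning(cfg, GRID, [hub])
        kinds = {ann.site_rc: ann.kind for ann in res.bursts}
        assert kinds.get((12, 12)) == "new_pattern"
        assert kinds.get((2, 2), "baseline") == "baseline"

    def test_hub_burst_distance_zero(self):
        cfg = SimulationConfig(
            seed=13, duration=120_000.0, burst_sites=((2, 2),), background_rate=0.0, latency_jitter_sd=0.0
        )
        hub = GRID.index(10, 10)
        res = simulate_post_learning(cfg, GRID, [hub])
        hub_bursts = [a for a in res.bursts if a.kind == "new_pattern"]
        assert hub_bursts
        for a in hub_bursts:
            assert a.site_index == hub

    def test_post_rate_doubles_pre(self):
        pre_n, post_n = [], []
        for seed in range(6):
            cfg = SimulationConfig(seed=seed, duration=300_000.0, background_rate=0.0, burst_sites=((8, 8),))
            pre_n.append(len(simulate_spontaneous(cfg, GRID).bursts))
            post_n.append(len(simulate_post_learning(cfg, GRID, [GRID.index(3, 3)]).bursts))
        ratio = np.sum(post_n) / np.sum(pre_n)
        assert 1.5 < ratio < 2.5

    def test_empty_hubs_warns(self):
        cfg = SimulationConfig(seed=1, duration=30_000.0, burst_sites=((8, 8),))
        with pytest.warns(UserWarning):
            simulate_post_learning(cfg, GRID, [])

    def test_bicuculline_longer_bursts(self):
        base = SimulationConfig(seed=21, duration=300_000.0, background_rate=0.0, burst_sites=((8, 8),))
        bic = dataclasses.replace(base, bicuculline_mode=True)
        d_base = np.mean([a.t_end - a.t0 for a in simulate_spontaneous(base, GRID).bursts])
        d_bic = np.mean([a.t_end - a.t0 for a in simulate_spontaneous(bic, GRID).bursts])
        assert d_bic > d_base


class TestLearningPhase:
    def test_requires_learning_set(self):
        with pytest.raises(ConfigError):
            simulate_learning_phase(SimulationConfig(), StimulationProtocol(), GRID)

    def test_certain_response_all_stimuli(self):
        cfg = SimulationConfig(
            seed=3, rs_start=1.0, rs_end=1.0, latency_jitter_sd=0.0, background_rate=0.0,
            learning_set=(0, 1, 2), rt_start=100.0, rt_end=50.0, nonlearning_response_prob=0.0,
        )
        proto = StimulationProtocol(n_cycles=2)
        res = simulate_learning_phase(cfg, proto, GRID)
        times = res.stimulus_log.times
        for e in (0, 1, 2):
            t = res.spike_set.train(e)
            for st in times:
                in_win = t[(t > st + 10.0) & (t <= st + 200.0)]
                assert in_win.size == 3  # the planted volley

    def test_flat_rt_zero_slope(self):
        from meaburst.learning import build_trial_response_table, localize

        cfg = SimulationConfig(
            seed=3, rs_start=1.0, rs_end=1.0, latency_jitter_sd=0.0, background_rate=0.0,
            learning_set=tuple(range(8)), rt_start=100.0, rt_end=99.999, nonlearning_response_prob=0.0,
        )
        res = simulate_learning_phase(cfg, StimulationProtocol(), GRID)
        table = build_trial_response_table(res.spike_set, res.stimulus_log)
        lmap = localize(table)
        idx = [list(table.electrodes).index(e) for e in range(8)]
        assert np.allclose(lmap.rt_slope[idx], 0.0, atol=1e-3)

    def test_learning_mask_matches_planted(self):
        cfg = SimulationConfig(seed=4, learning_set=(5, 6, 7))
        res = simulate_learning_phase(cfg, StimulationProtocol(n_cycles=1), GRID)
        assert res.learning_mask.sum() == 3
        assert set(np.flatnonzero(res.learning_mask)) == {5, 6, 7}

    def test_stream_independence(self):
        # disabling bursts must not change the background draws
        a = SimulationConfig(seed=8, duration=30_000.0, burst_rate=0.0, background_rate=0.5, burst_sites=((4, 4),))
        b = dataclasses.replace(a, burst_rate=8.0, burst_sites=((4, 4),))
        sa = simulate_spontaneous(a, GRID)
        sb = simulate_spontaneous(b, GRID)
        # every background spike of run a appears unchanged in run b
        for e in range(GRID.n_electrodes):
            ta = sa.spike_set.train(e)
            tb = sb.spike_set.train(e)
            assert np.all(np.isin(ta, tb))
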