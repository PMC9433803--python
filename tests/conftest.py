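import numpy as np
import pytest

from meaburst.core import ElectrodeGrid, SpikeTrainSet


@pytest.fixture
def small_grid():
    return ElectrodeGrid(n_rows=8, n_cols=8)


@pytest.fixture
def default_grid():
    return ElectrodeGrid()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_set(small_grid):
    """Three-electrode toy spike-train set."""
    return SpikeTrainSet(
        spikes={
            0: np.array([1.0, 5.0, 9.0]),
            3: np.array([2.5]),
            10: np.array([0.5, 7.25]),
        },
        duration=10.0,
        grid=small_grid,
        metadata={"phase": "before", "seed": 0},
    )


def random_spike_set(rng, grid, rate_hz=2.0, duration=5000.0, metadata=None):
    spikes = {}
    for e in range(grid.n_electrodes):
        n = rng.poisson(rate_hz * duration / 1000.0)
        if n:
            t = np.unique(rng.random(n) * duration)
            spikes[e] = t
    return SpikeTrainSet(spikes=spikes, duration=duration, grid=grid, metadata=metadata or {})
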