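import numpy as np
import pytest

from gammaring.cell import CellParams
from gammaring.network import TopologyConfig
from gammaring.simulator import RunConfig, SpikeData


@pytest.fixture(scope="session")
def cell_params() -> CellParams:
    return CellParams()


@pytest.fixture(scope="session")
def small_ring_config():
    """A 40-cell ring with the calibrated synapses: fast enough for unit
    tests while keeping the same dynamical regime."""
    def make(**overrides) -> RunConfig:
        defaults = dict(
            run_length=800.0, warmup=200.0,
            topology=TopologyConfig(n_cells=40, neighbourhood=20),
        )
        defaults.update(overrides)
        return RunConfig(**defaults)
    return make


def random_spike_data(n_cells: int, run_length: float, rate_hz: float,
                      seed: int) -> SpikeData:
    """Independent Poisson spike trains (test helper)."""
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n_cells):
        n = rng.poisson(rate_hz * run_length / 1000.0)
        trains.append(np.unique(np.sort(run_length * rng.random(n))))
    return SpikeData(n_cells=n_cells, run_length=run_length,
                     trains=tuple(trains))
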