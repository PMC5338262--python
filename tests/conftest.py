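import numpy as np
import pytest

from sexalloc import (
    EnvironmentMap,
    SimulationConfig,
    SpeciesTable,
    init_community,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_setup(rng):
    """A compact two-species community: 100 individuals in 2 demes."""
    config = SimulationConfig(
        n_individuals=100,
        n_demes=2,
        n_species=2,
        generations=0,
        mutation_rate=0.0,
        rng_seed=7,
    )
    table = SpeciesTable.ladder(2, hi=2.0, lo=1.0)
    env = EnvironmentMap.homogeneous(2)
    state = init_community(config, table, np.random.default_rng(7))
    return config, table, env, state
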