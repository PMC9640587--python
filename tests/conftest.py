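import numpy as np
import pytest

from cppmap.arena import ArenaSpec
from cppmap.synthetic import (
    ExperimentConfig,
    PopulationSpec,
    SimConfig,
    simulate_experiment,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def arena() -> ArenaSpec:
    return ArenaSpec()


@pytest.fixture(scope="session")
def short_traj(arena):
    """5-minute unbiased foraging trajectory."""
    return simulate_trajectory(arena, SimConfig(duration_s=300.0, seed=11))


@pytest.fixture(scope="session")
def small_experiment(arena):
    """Small planted experiment shared by integration-style tests."""
    spec = PopulationSpec(n_neurons=40, n_disappear_pref=6, n_untuned=8)
    return simulate_experiment(arena, spec, ExperimentConfig(duration_s=300.0, seed=21))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
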