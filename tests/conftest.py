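import numpy as np
import pytest

from barcodediv import run_lumping_experiment
from barcodediv.synthdata import SimulationConfig, simulate_species_tree


@pytest.fixture(scope="session")
def lumping_report():
    """The full-scale slow-marker lumping experiment (shared across tests)."""
    return run_lumping_experiment(
        scenario="pb", r=0.010, n_reps=10, tau=0.99, seed=1, crown_age=505.0
    )


@pytest.fixture(scope="session")
def yule_trees():
    """50 pure-birth trees at the study scale (lambda=0.01, T=505 Myr)."""
    return [
        simulate_species_tree(SimulationConfig(speciation_rate=0.010, seed=1000 + i))
        for i in range(50)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
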