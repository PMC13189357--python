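import numpy as np
import pytest

from fbmotility import MotilityParams, run_simulation


@pytest.fixture(scope="session")
def deterministic_params():
    """The noise-free benchmark configuration: 1000 steps of 0.1."""
    return MotilityParams(Dr=0.0, alpha=0.0, dt=0.1, n_steps=1000)


@pytest.fixture(scope="session")
def deterministic_trajectory(deterministic_params):
    return run_simulation(deterministic_params, seed=42)


@pytest.fixture(scope="session")
def deterministic_ensemble(deterministic_params):
    """A small ensemble of straight-line runs with random headings."""
    return [run_simulation(deterministic_params, seed=s, replicate_id=s)
            for s in range(12)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
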