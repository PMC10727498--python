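import numpy as np
import pytest

from sensilla import simulate
from sensilla.simulate import SimulationConfig, StimulusEffect


@pytest.fixture(scope="session")
def archetypes():
    return simulate.default_archetypes()


@pytest.fixture(scope="session")
def control_effect():
    return StimulusEffect("OSR")


@pytest.fixture(scope="session")
def small_config():
    """Small but complete simulated experiment (both stimuli, all locations)."""
    return SimulationConfig(seed=42, n_bees=3, sensilla_per_location=2, duration=1.2)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate.simulate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
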