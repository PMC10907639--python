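import numpy as np
import pytest

from samaraflight.synthetic_data import (GeneratorConfig, default_presets,
                                         generate_population)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=42)


@pytest.fixture(scope="session")
def default_population(default_config):
    """The shipped eight-species study population at the reference seed."""
    population, truth = generate_population(default_config)
    return population, truth


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
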