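import numpy as np
import pytest

from cardiovae.structures import split_dataset
from cardiovae.synthetic import GeneratorConfig, generate_population


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    """Very small resolution for fast unit tests."""
    return GeneratorConfig(n_points_per_class=48, ecg_length=100, seed=123)


@pytest.fixture(scope="session")
def tiny_population(tiny_config):
    return generate_population(12, 0, tiny_config)


@pytest.fixture(scope="session")
def tiny_split(tiny_population):
    return split_dataset(tiny_population, (0.75, 0.125, 0.125), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
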