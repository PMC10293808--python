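import numpy as np
import pytest

from agelength import (
    PopulationConfig,
    fit_loglinear_model,
    generate_population,
    paper_default_noise,
)


@pytest.fixture(scope="session")
def population():
    """Synthetic SDRP-like population: 263 animals, repeated assessments."""
    return generate_population(PopulationConfig(n_animals=263), seed=42)


@pytest.fixture(scope="session")
def loglinear_model(population):
    return fit_loglinear_model(population)


@pytest.fixture(scope="session")
def default_noise():
    return paper_default_noise()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
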