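import dataclasses

import numpy as np
import pytest

from capwave import CohortSpec, ModelConfig, TCNAttention, generate_cohort


@pytest.fixture(scope="session")
def noise_free_spec() -> CohortSpec:
    return dataclasses.replace(CohortSpec(), noise_sd=0.0)


@pytest.fixture(scope="session")
def small_cohort(noise_free_spec):
    """12 noise-free paired records, fixed seed, shared across tests."""
    return generate_cohort(12, noise_free_spec, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config() -> ModelConfig:
    return ModelConfig(k=2, num_levels=2, channels=3, dropout=0.0,
                       attention="channel", init_sd=0.3)


@pytest.fixture
def tiny_model(tiny_config) -> TCNAttention:
    return TCNAttention(tiny_config, seed=3)
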