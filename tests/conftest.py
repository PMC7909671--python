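import numpy as np
import pytest

from branchsim.games import GameParams, ModelConfig, singular_strategy


@pytest.fixture(scope="session")
def model() -> ModelConfig:
    """Two interchangeable games at the reference parameters."""
    return ModelConfig()


@pytest.fixture(scope="session")
def z_star(model) -> np.ndarray:
    return singular_strategy(model).z_star


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
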