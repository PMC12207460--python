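import numpy as np
import pytest

from thymosim import Grid, ModelParams


@pytest.fixture(scope="session")
def wt() -> ModelParams:
    """Wild-type parameter set."""
    return ModelParams()


@pytest.fixture(scope="session")
def grid2d_small() -> Grid:
    """Small 2D grid resolving the chemokine decay length."""
    return Grid.make(2, 32, 750.0)


@pytest.fixture(scope="session")
def grid2d_medium() -> Grid:
    return Grid.make(2, 64, 1500.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
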