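import numpy as np
import pytest

from chainrank import FeatureMatrix, preset, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """A 10x5 positive abundance-like matrix."""
    values = rng.lognormal(0, 1, size=(10, 5))
    return FeatureMatrix(
        values, [f"S{i}" for i in range(10)], [f"F{j}" for j in range(5)]
    )


@pytest.fixture(scope="session")
def dataset1_like():
    """One dataset1-shaped synthetic cohort, shared across tests."""
    return simulate(preset("dataset1-like", seed=7))
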