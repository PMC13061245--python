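import numpy as np
import pytest

from scrumforce.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def synthetic_pairs_200():
    """200 simulated velocity-force pairs (with ground truth), session-cached."""
    return simulate_dataset(SimConfig(n_trials=200, seed=7))


@pytest.fixture(scope="session")
def pairs_200(synthetic_pairs_200):
    return [p for p, _ in synthetic_pairs_200]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
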