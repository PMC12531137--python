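import numpy as np
import pytest

from dhclham import RunConfig, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_synth():
    """Small planted-structure dataset for fast unit tests."""
    return generate_dataset(SyntheticSpec(n_microbes=30, n_drugs=40, target_density=0.08, seed=1))


@pytest.fixture()
def tiny_config():
    """Config small enough for sub-second training runs."""
    return RunConfig(embed_dim=8, epochs=3, n_heads=2, knn_k=3, ko_c=3, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
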