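import numpy as np
import pytest

from trustomics import RunConfig, SyntheticSpec, generate


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small well-separated 3-class dataset shared by the fast tests."""
    spec = SyntheticSpec(n_samples=60, n_classes=3, n_features=(12, 10, 8),
                         informative_fraction=0.3, effect_size=3.0, seed=7)
    dataset, manifest = generate(spec)
    return dataset, manifest


@pytest.fixture
def fast_config():
    return RunConfig(epochs=30, k_neighbors=6, learning_rate=5e-3,
                     annealing_step=10, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
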