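import numpy as np
import pytest

import boldfusion as bf
from boldfusion.resnet import ResNet50Features


@pytest.fixture(scope="session")
def tiny_pool():
    """Small balanced pool (4 classes x 6 signals, 4 subjects) for unit tests."""
    return bf.generate_pool(n_per_class=6, n_subjects=4, seed=11)


@pytest.fixture(scope="session")
def tiny_conditioned(tiny_pool):
    return tiny_pool.conditioned()


@pytest.fixture(scope="session")
def resnet_encoder():
    """One shared fixed-weight CNN instance (construction costs seconds)."""
    return ResNet50Features(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
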