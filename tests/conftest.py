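import numpy as np
import pytest

from nodulehash.model import NoduleRetrieval, RetrievalConfig
from nodulehash.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_train():
    return generate_dataset(40, 40, master_seed=11)


@pytest.fixture(scope="session")
def small_test():
    return generate_dataset(15, 15, master_seed=202)


@pytest.fixture(scope="session")
def small_config():
    return RetrievalConfig(
        bits=16, n_clusters=5, m_candidates=3, p=5, m_anchor=40, l_label_samples=80
    )


@pytest.fixture(scope="session")
def fitted(small_train, small_config):
    """A fitted retrieval index over the small synthetic training set."""
    return NoduleRetrieval.from_images(small_train, small_config).fit(seed=0)


@pytest.fixture(scope="session")
def small_features(fitted):
    """Raw (unstandardized) training feature matrix of the fitted index."""
    return fitted.model.X


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
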