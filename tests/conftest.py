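import numpy as np
import pytest

from dermseg.synthetic import SyntheticConfig, generate_samples


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_samples():
    """Eight 64x64 synthetic dermoscopy samples shared across tests."""
    return generate_samples(SyntheticConfig(n_samples=8, size=(64, 64), seed=99))


@pytest.fixture(scope="session")
def one_sample(small_samples):
    return small_samples[0]
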