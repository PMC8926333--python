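import numpy as np
import pytest

from fairconn.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """Small but fully structured population: 2 groups + other, families, sites."""
    return SyntheticConfig(
        n_majority=80, n_minority=24, n_other=8, n_roi=12, n_sites=3, seed=7
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
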