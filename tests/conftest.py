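import logging

import pytest

from ribotax import SyntheticConfig, simulate_dataset

logging.getLogger("ribotax").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared across tests."""
    return simulate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset for fast unit tests (fewer sites/specimens)."""
    config = SyntheticConfig(
        n_sites=8, specimens_per_site=(2, 4), clones_per_specimen=(6, 10),
        seq_length=500, seed=7,
    )
    return simulate_dataset(config)
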