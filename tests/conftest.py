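import numpy as np
import pytest

from sheddetect import SimConfig, generate_paired_omics


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale study for fast unit tests (same structure as defaults)."""
    return SimConfig(n_genes=400, n_proteins=300, n_paired=240, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_paired_omics(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
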