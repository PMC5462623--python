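import numpy as np
import pytest

from skullqtl import simdata


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: 150 dogs, 6 breeds, 400 markers, 24 landmarks."""
    return simdata.SimConfig(
        n_dogs=150,
        n_breeds=6,
        n_snps=400,
        ld_block_len=20,
        n_landmarks=24,
        qtl_effect=0.06,
        noise_sd=0.01,
        seed=7,
        n_case_breeds=2,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simdata.simulate_study(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
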