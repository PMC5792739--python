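import numpy as np
import pytest

from crossmeta import synthetic as syn


@pytest.fixture(scope="session")
def small_fixture():
    """A reduced end-to-end study shared by fast integration tests."""
    return syn.make_end_to_end_fixture(17, n_patients=250, n_genes=300,
                                       n_concordant=10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
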