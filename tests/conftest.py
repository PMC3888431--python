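import numpy as np
import pytest

from txconsolidate.synthetic import GenomeParams, make_genome


@pytest.fixture(scope="session")
def small_bundle():
    """A 12-gene toy genome with isoforms, shared across tests."""
    return make_genome(12, seed=7)


@pytest.fixture(scope="session")
def single_isoform_bundle():
    """A 10-gene toy genome with one isoform per gene."""
    return make_genome(10, seed=17, params=GenomeParams(isoforms=(1, 1)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_nt(rng, n: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n).tobytes().decode()
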