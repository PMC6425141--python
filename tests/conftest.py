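import numpy as np
import pytest

from l1trace import sim


@pytest.fixture(scope="session")
def full_l1():
    return sim.make_l1_body()


@pytest.fixture(scope="session")
def mini_l1():
    return sim.make_l1_body(mini=True)


@pytest.fixture(scope="session")
def genome():
    return sim.make_genome(11, {"chr1": 6000, "chr2": 4000})


@pytest.fixture(scope="session")
def de_novo(full_l1):
    """Worked-example de novo locus: (genome, truth record, donor flank)."""
    return sim.de_novo_fixture(101, l1=full_l1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
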