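import numpy as np
import pytest

import viromekit as vk
from viromekit.seqio import ReadSet


@pytest.fixture(scope="session")
def small_community():
    return vk.make_community(5, 2000, "power", {"b": 1.0}, seed=11)


@pytest.fixture(scope="session")
def small_readset(small_community):
    p = vk.ReadSimParams(n_reads=200, read_len=100, seed=7)
    return vk.simulate_reads(small_community, p, name="small")


@pytest.fixture()
def toy_reads():
    return ReadSet(name="toy", reads=[
        ("a", "ACGTACGTACGT"),
        ("b", "TTTTGGGGCCCC"),
        ("c", "ACGTACGTACGT"),
    ])


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
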