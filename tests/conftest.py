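import numpy as np
import pytest

from proviscope.genome_io import Contig


AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20110510)


def random_protein(rng, n):
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@pytest.fixture
def random_contig(rng):
    return Contig("rnd", random_dna(rng, 2000))
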