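import numpy as np
import pytest

from mitocomp.ancestry import read_newick
from mitocomp.synthetic_data import SimConfig, default_trna_template, generate_toy_mitogenome

#: the 22 mitochondrial tRNA family tokens
TRNA_TOKENS = sorted(
    "trn" + x for x in
    ["A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2", "M",
     "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y"]
)


@pytest.fixture
def cfg():
    return SimConfig(seed=11)


@pytest.fixture
def quartet_tree():
    return read_newick("((A,B),(C,D));")


@pytest.fixture
def template():
    return default_trna_template("trnA")


@pytest.fixture(scope="session")
def toy_genome():
    genome, log = generate_toy_mitogenome(SimConfig(seed=11))
    return genome, log


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
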