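import numpy as np
import pytest

from mirtarget import MiRNA, NucSequence, read_newick
from mirtarget.thermodynamics import NNBackend, load_nn_table


@pytest.fixture(scope="session")
def mirna() -> MiRNA:
    # let-7-family-like guide; seed 2-7 = GGAAUG, seed 2-8 = GGAAUGU
    return MiRNA(name="mir-x", residues="UGGAAUGUAAAGAAGUAUGUAU")


@pytest.fixture(scope="session")
def nn_table():
    return load_nn_table()


@pytest.fixture(scope="session")
def backend(nn_table) -> NNBackend:
    return NNBackend(nn_table)


@pytest.fixture(scope="session")
def toy_tree():
    return read_newick("((A:0.1,B:0.2):0.3,C:0.4);")


@pytest.fixture(scope="session")
def mammal_tree():
    # 7-species tree with mammal-like branch lengths (subs/site)
    return read_newick(
        "(((((human:0.08,chimp:0.09):0.12,mouse:0.35):0.1,"
        "(cow:0.25,dog:0.22):0.08):0.15,opossum:0.55):0.2,chicken:0.9);"
    )


def random_rna(rng: np.random.Generator, length: int, alphabet: str = "ACGU") -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


@pytest.fixture(scope="session")
def rna_factory():
    return random_rna
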