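import numpy as np
import pytest

from pairzyme.chem import parse_mapped_reaction
from pairzyme.embeddings import train_cbow
from pairzyme.synth import SyntheticSpec, gen_triad_dataset


@pytest.fixture(scope="session")
def ethanol_oxidation():
    return parse_mapped_reaction(
        "[CH3:1][CH2:2][OH:3]>>[CH3:1][CH:2]=[O:3]", "r_ox", ["1.1.1.1"]
    )


@pytest.fixture(scope="session")
def condensation():
    # methanol + methanol -> dimethyl ether + water
    return parse_mapped_reaction(
        "[CH3:1][OH:2].[CH3:3][OH:4]>>[CH3:1][O:2][CH3:3].[OH2:4]", "r_cond"
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-signal dataset shared by dataset-level tests."""
    return gen_triad_dataset(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def cbow_table(tiny_dataset):
    sequences = sorted({t.enzyme.sequence for t in tiny_dataset.triads})[:40]
    return train_cbow(sequences, epochs=2, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
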