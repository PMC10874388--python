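import numpy as np
import pytest

from pepgroove import synth
from pepgroove.structio import select


@pytest.fixture(scope="session")
def toy_complex():
    """Standard planted complex: 3 contacts, 1 H-bond, 1 salt bridge."""
    spec = synth.ToyComplexSpec(
        n_receptor=12,
        n_ligand=7,
        contacts=(2, 5, 8),
        hbonds=(10,),
        salt_bridges=(4,),
        seed=11,
    )
    return synth.make_toy_complex(spec)


@pytest.fixture(scope="session")
def toy_ligand(toy_complex):
    structure, _ = toy_complex
    return select(structure, "chain B")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
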