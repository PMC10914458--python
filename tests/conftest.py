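import numpy as np
import pytest

from protabc.fixture import generate_fixture, make_chain_structure
from protabc.structure import build_stability_model, load_contact_potential


@pytest.fixture(scope="session")
def potential():
    return load_contact_potential()


@pytest.fixture(scope="session")
def small_structure():
    return make_chain_structure(30, seed=42)


@pytest.fixture(scope="session")
def small_stab(small_structure, potential):
    return build_stability_model(
        small_structure, potential=potential, n_decoys=50, decoy_seed=42
    )


@pytest.fixture(scope="session")
def scenario():
    """Shared L=60 / n=12 synthetic scenario (neutral ground truth)."""
    return generate_fixture(11, L=60, n=12, true_model="neutral")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_sequence(rng, length):
    from protabc.alphabet import AMINO_ACIDS

    return "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=length))
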