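import numpy as np
import pytest

from mtphylo import load_reference, q2a_preset
from mtphylo.alignment import Alignment

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@pytest.fixture(scope="session")
def ref_and_map():
    return load_reference()


@pytest.fixture(scope="session")
def reference(ref_and_map):
    return ref_and_map[0]


@pytest.fixture(scope="session")
def gene_map(ref_and_map):
    return ref_and_map[1]


@pytest.fixture(scope="session")
def preset():
    """One shared Q2a-like synthetic dataset (alignment + truth)."""
    return q2a_preset(seed=11)


def random_alignment(rng, n_taxa, n_cols, n_states=4, taxa=None):
    mat = rng.choice(_BASES[:n_states], size=(n_taxa, n_cols))
    return Alignment(
        taxa=taxa or [f"t{i}" for i in range(n_taxa)],
        matrix=mat,
        column_positions=np.arange(1, n_cols + 1),
    )


@pytest.fixture
def make_alignment():
    return random_alignment
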