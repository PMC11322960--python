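import numpy as np
import pytest

from graphff.chemgraph import parse_molecule
from graphff.fixtures import ReferenceForceField, build_fixture_set


@pytest.fixture(scope="session")
def ref_ff():
    return ReferenceForceField()


@pytest.fixture(scope="session")
def lj_table(ref_ff):
    return ref_ff.lj_table()


@pytest.fixture(scope="session")
def small_dataset(ref_ff):
    """A 4-molecule, 6-conformer dataset for fast unit tests."""
    return build_fixture_set(seed=11, n_conformers=6,
                             smiles=("CCO", "CC=O", "c1ccccc1", "CC(=O)[O-]"))


@pytest.fixture(scope="session")
def fixture_dataset():
    """The full synthetic dataset (shared by acceptance-level tests)."""
    return build_fixture_set(seed=101, n_conformers=25)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ethanol():
    return parse_molecule("CCO")
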