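import numpy as np
import pytest

from mmcompress.structure_model import (
    Atom,
    CoordinateArrays,
    Grouping,
    Molecule,
    StructureSet,
)
from mmcompress.synthetic_fixtures import (
    FixtureSpec,
    make_complex,
    make_ensemble,
    make_polymer,
)


@pytest.fixture
def polymer():
    return make_polymer(FixtureSpec(seed=42, n_atoms=500))


@pytest.fixture
def polymer_set(polymer):
    return StructureSet([polymer], label="polymer", grouping=Grouping.CHAINS)


@pytest.fixture
def ensemble():
    return make_ensemble(FixtureSpec(seed=7, n_atoms=200, n_models=10, noise_sd=0.05))


@pytest.fixture
def unaligned_ensemble():
    return make_ensemble(
        FixtureSpec(seed=8, n_atoms=150, n_models=6, noise_sd=0.05, apply_random_rigid=True)
    )


@pytest.fixture
def complex_set():
    return make_complex(FixtureSpec(seed=9, n_atoms=120, n_subunits=4, noise_sd=0.02))


@pytest.fixture
def mixed_chain():
    """Two amino-acid residues followed by two nucleotides, several atoms each."""
    atoms = [
        Atom("N", "N", 1, "ALA", "A"),
        Atom("CA", "C", 1, "ALA", "A"),
        Atom("C", "C", 1, "ALA", "A"),
        Atom("N", "N", 2, "GLY", "A"),
        Atom("CA", "C", 2, "GLY", "A"),
        Atom("C", "C", 2, "GLY", "A"),
        Atom("P", "P", 3, "DA", "B"),
        Atom("O5'", "O", 3, "DA", "B"),
        Atom("C5'", "C", 3, "DA", "B"),
        Atom("P", "P", 4, "DG", "B"),
        Atom("O5'", "O", 4, "DG", "B"),
    ]
    rng = np.random.default_rng(0)
    pts = np.round(np.cumsum(rng.normal(0, 1, (len(atoms), 3)), axis=0), 3)
    return Molecule(atoms, CoordinateArrays.from_matrix(pts))
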