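"""Shared fixtures: synthetic cavity structures and detected pockets."""

import numpy as np
import pytest

from pockalign.fixtures import FixtureSpec, make_cavity_protein
from pockalign.pocket_model import detect_pocket
from pockalign.surface_model import ses_contributing_atoms


@pytest.fixture(scope="session")
def cavity_spec():
    return FixtureSpec(shell_radius=12.0, cavity_radius=4.0,
                       cavity_direction=np.array([1.0, 0.0, 0.0]),
                       atom_spacing=3.0, ligand_atom_count=3, seed=1)


@pytest.fixture(scope="session")
def cavity_structure(cavity_spec):
    return make_cavity_protein(cavity_spec)


@pytest.fixture(scope="session")
def cavity_surface(cavity_structure):
    return ses_contributing_atoms(cavity_structure)


@pytest.fixture(scope="session")
def cavity_pocket(cavity_structure, cavity_surface):
    return detect_pocket(cavity_structure, surface=cavity_surface)


@pytest.fixture(scope="session")
def dense_spec():
    # denser cloud and wider cavity: pocket detection is stable under
    # rotation of the whole structure, which recovery checks rely on
    return FixtureSpec(shell_radius=12.0, cavity_radius=4.5,
                       cavity_direction=np.array([1.0, 0.0, 0.0]),
                       atom_spacing=2.6, ligand_atom_count=4, seed=7)


@pytest.fixture(scope="session")
def dense_structure(dense_spec):
    return make_cavity_protein(dense_spec)


@pytest.fixture(scope="session")
def dense_pocket(dense_structure):
    return detect_pocket(dense_structure)
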