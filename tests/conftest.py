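"""Shared fixtures: all structural test data is generated programmatically."""

import warnings

import numpy as np
import pytest
import biotite.structure as struc

from abdock.structure import Structure, compute_asa
from abdock.synthetic import ToyComplexSpec, make_toy_complex

warnings.filterwarnings("ignore", message="missing backbone atom")


def chain_structure(coords_per_residue, chain="A", res_names=None, elements=None):
    """Build a Structure from a list of {atom_name: xyz} dicts (one per residue)."""
    n_atoms = sum(len(d) for d in coords_per_residue)
    atoms = struc.AtomArray(n_atoms)
    atoms.coord = np.zeros((n_atoms, 3))
    a = 0
    for i, residue in enumerate(coords_per_residue):
        name = (res_names or ["ALA"] * len(coords_per_residue))[i]
        for atom_name, xyz in residue.items():
            atoms.chain_id[a] = chain
            atoms.res_id[a] = i + 1
            atoms.res_name[a] = name
            atoms.atom_name[a] = atom_name
            atoms.element[a] = (elements or {}).get(atom_name, atom_name[0])
            atoms.coord[a] = xyz
            a += 1
    atoms.hetero[:] = False
    return Structure(atoms, id="test")


def ca_only_chain(ca_coords, chain="A", res_names=None):
    return chain_structure(
        [{"CA": c} for c in np.asarray(ca_coords, dtype=float)],
        chain=chain,
        res_names=res_names,
    )


@pytest.fixture(scope="session")
def toy_complex():
    """One deterministic planted-interface complex shared across tests."""
    tc = make_toy_complex(ToyComplexSpec(seed=7, interface_size=8))
    for s in (tc.ab, tc.ag, tc.ab_model, tc.ag_model):
        compute_asa(s)
    return tc


@pytest.fixture(scope="session")
def toy_reference(toy_complex):
    return toy_complex.reference()
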