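"""Shared fixtures: tiny hand-built structures and synthetic ensembles."""

import numpy as np
import pytest

from idpensemble import Atom, StructureModel
from idpensemble.synthetic_ensembles import (disordered_ensemble,
                                             make_reference_chain,
                                             ordered_ensemble)


def build_model(positions_by_residue, model_id="toy", chain_id="A",
                resname="GLY", confidence=90.0):
    """Model from a list of residues, each a list of (x, y, z) heavy atoms."""
    atoms = []
    for r, residue_atoms in enumerate(positions_by_residue, start=1):
        for a, pos in enumerate(residue_atoms):
            atoms.append(Atom(chain_id=chain_id, residue_index=r,
                              insertion_code="", residue_name=resname,
                              atom_name=f"C{a}" if a else "CA", element="C",
                              position=tuple(float(v) for v in pos),
                              confidence=confidence))
    return StructureModel(model_id, atoms)


def random_model(rng, n_residues, atoms_per_residue=(1, 4), box=25.0,
                 model_id="random"):
    """Random atom-cloud model: residues with 1..k heavy atoms in a box."""
    residues = []
    for _ in range(n_residues):
        k = int(rng.integers(atoms_per_residue[0], atoms_per_residue[1] + 1))
        residues.append(rng.uniform(-box, box, size=(k, 3)))
    return build_model(residues, model_id=model_id)


@pytest.fixture(scope="session")
def compact_reference():
    return make_reference_chain(60, compactness=0.5, seed=11)


@pytest.fixture(scope="session")
def ordered_fixture(compact_reference):
    return ordered_ensemble(compact_reference, sigma=0.2, n_members=12,
                            seed=21)


@pytest.fixture(scope="session")
def disordered_fixture():
    return disordered_ensemble(n_residues=80, n_members=10, seed=31)
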