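import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from insertscan.structure_model import Atom, ProteinStructure, Residue
from insertscan.synthetic_data import (extended_chain_structure,
                                       ideal_helix_structure)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def helix12():
    return ideal_helix_structure(12)


@pytest.fixture(scope="session")
def extended12():
    return extended_chain_structure(12)


@pytest.fixture(scope="session")
def crambin_like():
    """46-residue scaffold with two helices at crambin's annotated spans."""
    st = ideal_helix_structure(46)
    st.helix_ranges = [(7, 17), (23, 30)]
    st.__post_init__()
    return st


def make_structure(residue_specs, helix_ranges=()):
    """Assemble a ProteinStructure from [(resname, [(atom, element, xyz)])]."""
    residues = []
    serial = 0
    for i, (name, atom_specs) in enumerate(residue_specs, start=1):
        atoms = []
        for atom_name, element, xyz in atom_specs:
            serial += 1
            atoms.append(Atom(serial, atom_name, element,
                              np.asarray(xyz, float), i, "A"))
        residues.append(Residue(i, name, atoms))
    return ProteinStructure(residues, list(helix_ranges), source_id="fixture")
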