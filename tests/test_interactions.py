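import numpy as np
import pytest

from insertscan.geometry import random_rotation
from insertscan.interactions import (InteractionConfig, covalent_bonds,
                                     detect_hbonds, detect_hydrophobics,
                                     hbond_count)
from conftest import make_structure


def _gly(xyz):
    x, y, z = xyz
    return ("GLY", [("N", "N", (x, y, z)),
                    ("CA", "C", (x + 1.458, y, z)),
                    ("C", "C", (x + 2.0, y + 1.4, z)),
                    ("O", "O", (x + 3.2, y + 1.5, z))])


def test_distant_glycines_have_no_hbonds():
    st = make_structure([_gly((0, 0, 0)), _gly((10, 10, 10))])
    assert hbond_count(st) == 0


def test_ideal_helix_backbone_bonds(helix12):
    """The 12-residue ideal helix has exactly the 8 i -> i-4 backbone bonds."""
    bonds = detect_hbonds(helix12)
    assert len(bonds) == 8
    pairs = set()
    for b in bonds:
        donor = b.atom_a if b.atom_a.element == "N" else b.atom_b
        acceptor = b.atom_b if b.atom_a.element == "N" else b.atom_a
        assert donor.name == "N" and acceptor.name == "O"
        pairs.add((donor.residue_index, acceptor.residue_index))
    assert pairs == {(i, i - 4) for i in range(5, 13)}


def test_extended_chain_has_no_hbonds(extended12):
    assert hbond_count(extended12) == 0


def test_constructed_collinear_hbond():
    """Carbonyl O and amide N 2.9 Å apart with a collinear H: one bond."""
    donor_res = ("ALA", [("N", "N", (0.0, 0.0, 0.0)),
                         ("H", "H", (-1.01, 0.0, 0.0)),
                         ("CA", "C", (0.8, 1.2, 0.0)),
                         ("C", "C", (2.2, 1.3, 0.0)),
                         ("O", "O", (3.0, 2.2, 0.0))])
    spacer_res = ("GLY", [("N", "N", (50.0, 50.0, 50.0)),
                          ("CA", "C", (51.5, 50.0, 50.0)),
                          ("C", "C", (52.0, 51.4, 50.0)),
                          ("O", "O", (53.2, 51.5, 50.0))])
    acceptor_res = ("ALA", [("N", "N", (-6.5, 0.0, 0.0)),
                            ("CA", "C", (-5.8, -1.2, 0.0)),
                            ("C", "C", (-4.4, -1.1, 0.0)),
                            ("O", "O", (-2.9, 0.0, 0.0))])
    # a far-away spacer keeps donor and acceptor in non-adjacent residues
    # (a carbonyl O is always 1-3 to the next residue's amide N)
    st = make_structure([acceptor_res, spacer_res, donor_res])
    bonds = detect_hbonds(st)
    hb = [b for b in bonds
          if {b.atom_a.name, b.atom_b.name} == {"N", "O"}
          and b.atom_a.residue_index != b.atom_b.residue_index]
    assert len(hb) == 1


def test_rigid_transform_invariance(helix12):
    rng = np.random.default_rng(11)
    rot = random_rotation(rng)
    moved = helix12.transformed(rot, rng.uniform(-30, 30, 3))
    assert hbond_count(moved) == hbond_count(helix12)
    assert len(detect_hydrophobics(moved)) == len(detect_hydrophobics(helix12))


def test_cb_tether_distance_threshold():
    """Isolated Cβ atoms 3.5 Å apart: tether; 4.0 Å: none (cutoff 3.65)."""
    near = make_structure([("ALA", [("CB", "C", (0, 0, 0))]),
                           ("ALA", [("CB", "C", (3.5, 0, 0))])])
    far = make_structure([("ALA", [("CB", "C", (0, 0, 0))]),
                          ("ALA", [("CB", "C", (4.0, 0, 0))])])
    assert len(detect_hydrophobics(near)) == 1
    assert len(detect_hydrophobics(far)) == 0


def test_no_intra_residue_tethers():
    st = make_structure([("ALA", [("CB", "C", (0, 0, 0)),
                                  ("CA", "C", (1.5, 0, 0))])])
    assert detect_hydrophobics(st) == []


def test_interaction_lists_are_symmetric_pair_sets(helix12):
    for detector in (detect_hbonds, detect_hydrophobics):
        pairs = [i.pair for i in detector(helix12)]
        assert len(pairs) == len(set(pairs))
        assert all(a < b for a, b in pairs)


def test_atom_reordering_invariance(helix12):
    """Reversing per-residue atom order does not change detected counts."""
    from insertscan.structure_model import ProteinStructure, Residue
    reordered = ProteinStructure(
        [Residue(r.index, r.name, list(reversed(r.atoms)))
         for r in helix12.residues],
        list(helix12.helix_ranges), helix12.source_id)
    assert hbond_count(reordered) == hbond_count(helix12)


def test_loosening_cutoff_is_monotone(helix12):
    counts = [hbond_count(helix12, InteractionConfig(hbond_max_dist=d))
              for d in (3.0, 3.2, 3.5, 3.8, 4.2)]
    assert counts == sorted(counts)


def test_covalent_topology_of_single_glycine():
    st = make_structure([_gly((0, 0, 0))])
    bonds = covalent_bonds(st)
    names = {tuple(sorted((b.atom_a.name, b.atom_b.name))) for b in bonds}
    assert names == {("CA", "N"), ("C", "CA"), ("C", "O")}
    locked = {tuple(sorted((b.atom_a.name, b.atom_b.name)))
              for b in bonds if b.locked}
    assert locked == {("C", "O")}
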