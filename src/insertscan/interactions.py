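"""Detection of stabilizing interactions.

Three kinds of interaction parameterize the mechanical model:

* covalent bonds, inferred from residue bond templates plus inter-residue
  peptide bonds (locked bonds merge atoms into one rigid body, rotatable
  bonds become hinges);
* hydrogen bonds, from a geometric donor/acceptor criterion (distance plus
  either an explicit D-H...A angle or, for unprotonated files, antecedent
  angles at the donor);
* hydrophobic tethers between carbon/sulfur atoms of different residues
  within van der Waals contact plus a small slack.

The hydrogen-bond count (HBC) doubles as a per-structure stability proxy:
between two mutants, the one with more hydrogen bonds is taken to be the
more stable.  The detector here is geometric, not energy-based, so absolute
counts are not comparable with energy-scored tallies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chem import VDW_RADIUS, acceptor_atoms, donor_atoms, residue_bonds
from .structure_model import Atom, ProteinStructure


@dataclass(frozen=True)
class Interaction:
    kind: str  # "covalent", "hbond", "hydrophobic"
    atom_a: Atom
    atom_b: Atom
    bars: int
    locked: bool = False  # covalent only: merges bodies when True

    def __post_init__(self):
        if self.bars < 1:
            raise ValueError("bars must be >= 1")
        if self.atom_a.serial == self.atom_b.serial:
            raise ValueError("self-interaction")

    @property
    def pair(self) -> tuple[int, int]:
        a, b = self.atom_a.serial, self.atom_b.serial
        return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class InteractionConfig:
    """Geometric cutoffs and bar multiplicities (body-bar-hinge conventions)."""
    hbond_max_dist: float = 3.5       # donor-acceptor heavy-atom distance, Å
    hbond_min_dha: float = 120.0      # D-H...A angle at H, degrees
    hbond_min_antecedent: float = 90.0  # antecedent-D...A angle, no explicit H
    hydrophobic_slack: float = 0.25   # added to vdW radius sum, Å
    hinge_bars: int = 5               # rotatable covalent bond
    hbond_bars: int = 5
    hydrophobic_bars: int = 2


DEFAULT_CONFIG = InteractionConfig()


def covalent_bonds(structure: ProteinStructure) -> list[Interaction]:
    """Covalent topology: template bonds, peptide links, hydrogen attachments.

    Hydrogens are attached (locked) to the nearest heavy atom in their
    residue.  Consecutive residues are joined by a locked peptide C-N bond.
    """
    bonds: list[Interaction] = []
    for res in structure.residues:
        by_name = {a.name: a for a in res.atoms}
        for a_name, b_name, locked in residue_bonds(res.name):
            if a_name in by_name and b_name in by_name:
                bonds.append(Interaction("covalent", by_name[a_name],
                                         by_name[b_name],
                                         bars=6 if locked else DEFAULT_CONFIG.hinge_bars,
                                         locked=locked))
        heavies = [a for a in res.atoms if a.element != "H"]
        for a in res.atoms:
            if a.element == "H" and heavies:
                parent = min(heavies,
                             key=lambda h: float(np.linalg.norm(h.coords - a.coords)))
                bonds.append(Interaction("covalent", parent, a, bars=6, locked=True))
    for r1, r2 in zip(structure.residues, structure.residues[1:]):
        c = r1.atom("C")
        n = r2.atom("N")
        if c is not None and n is not None:
            bonds.append(Interaction("covalent", c, n, bars=6, locked=True))
    return bonds


def _adjacency(bonds: list[Interaction]) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {}
    for b in bonds:
        adj.setdefault(b.atom_a.serial, set()).add(b.atom_b.serial)
        adj.setdefault(b.atom_b.serial, set()).add(b.atom_a.serial)
    return adj


def detect_hbonds(structure: ProteinStructure,
                  config: InteractionConfig = DEFAULT_CONFIG) -> list[Interaction]:
    """Geometric hydrogen bonds as donor-acceptor Interactions.

    Donor heavy atoms come from residue templates (backbone amide N of every
    non-proline residue plus standard side-chain donors) or from explicit
    attached hydrogens; acceptors are lone-pair bearers (carbonyl/side-chain
    O, S, unprotonated ring N).  A pair qualifies when the heavy-atom
    distance is within the cutoff and the angular test passes; covalent and
    1-3 pairs are excluded, and each unordered pair is reported once.
    """
    bonds = covalent_bonds(structure)
    adj = _adjacency(bonds)
    atoms_by_serial = {a.serial: a for a in structure.atoms}

    donors: list[Atom] = []
    acceptors: list[Atom] = []
    for res in structure.residues:
        dnames = donor_atoms(res.name)
        anames = acceptor_atoms(res.name)
        for a in res.atoms:
            if a.element not in ("N", "O", "S"):
                continue
            has_h = any(atoms_by_serial[s].element == "H"
                        for s in adj.get(a.serial, ()))
            if a.name in dnames or has_h:
                donors.append(a)
            if a.name in anames:
                acceptors.append(a)
    if not donors or not acceptors:
        return []

    acc_coords = np.array([a.coords for a in acceptors])
    tree = cKDTree(acc_coords)
    seen: set[tuple[int, int]] = set()
    out: list[Interaction] = []
    for d in donors:
        d_nbrs = adj.get(d.serial, set())
        h_atoms = [atoms_by_serial[s] for s in d_nbrs
                   if atoms_by_serial[s].element == "H"]
        antecedents = [atoms_by_serial[s] for s in d_nbrs
                       if atoms_by_serial[s].element != "H"]
        for j in tree.query_ball_point(d.coords, config.hbond_max_dist):
            a = acceptors[j]
            if a.serial == d.serial or a.serial in d_nbrs:
                continue
            if d_nbrs & adj.get(a.serial, set()):
                continue  # 1-3 pair
            if h_atoms:
                ok = any(_angle(d.coords, h.coords, a.coords) >= config.hbond_min_dha
                         for h in h_atoms)
            else:
                ok = all(_angle(x.coords, d.coords, a.coords) >= config.hbond_min_antecedent
                         for x in antecedents)
            if not ok:
                continue
            key = (min(d.serial, a.serial), max(d.serial, a.serial))
            if key in seen:
                continue
            seen.add(key)
            out.append(Interaction("hbond", d, a, bars=config.hbond_bars))
    out.sort(key=lambda i: i.pair)
    return out


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    if denom == 0:
        return 0.0
    return float(np.degrees(np.arccos(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0))))


def hbond_count(structure: ProteinStructure,
                config: InteractionConfig = DEFAULT_CONFIG) -> int:
    """HBC: the number of detected hydrogen bonds."""
    return len(detect_hbonds(structure, config))


def detect_hydrophobics(structure: ProteinStructure,
                        config: InteractionConfig = DEFAULT_CONFIG) -> list[Interaction]:
    """Hydrophobic tethers: inter-residue C/S atom pairs in vdW contact.

    Pairs within three covalent bonds of each other (1-2, 1-3 and 1-4, e.g.
    backbone atoms of consecutive residues across the peptide bond) are
    never tethers: a 1-4 distance is fixed by a single torsion and is not a
    stabilizing contact.
    """
    candidates = [a for a in structure.atoms if a.element in VDW_RADIUS]
    out: list[Interaction] = []
    if len(candidates) < 2:
        return out
    adj = _adjacency(covalent_bonds(structure))

    def _within_three_bonds(sa: int, sb: int) -> bool:
        frontier = {sa}
        for _ in range(3):
            frontier = {n for f in frontier for n in adj.get(f, ())} | frontier
            if sb in frontier:
                return True
        return False

    coords = np.array([a.coords for a in candidates])
    max_cut = 2 * VDW_RADIUS["S"] + config.hydrophobic_slack
    tree = cKDTree(coords)
    for i, j in sorted(tree.query_pairs(max_cut)):
        a, b = candidates[i], candidates[j]
        if a.residue_index == b.residue_index:
            continue
        if _within_three_bonds(a.serial, b.serial):
            continue
        cutoff = VDW_RADIUS[a.element] + VDW_RADIUS[b.element] + config.hydrophobic_slack
        if np.linalg.norm(a.coords - b.coords) <= cutoff:
            out.append(Interaction("hydrophobic", a, b, bars=config.hydrophobic_bars))
    out.sort(key=lambda i: i.pair)
    return out


def all_interactions(structure: ProteinStructure,
                     config: InteractionConfig = DEFAULT_CONFIG) -> list[Interaction]:
    """Covalent + hydrogen-bond + hydrophobic interactions for the model."""
    return (covalent_bonds(structure)
            + detect_hbonds(structure, config)
            + detect_hydrophobics(structure, config))
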