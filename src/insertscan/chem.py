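"""Amino-acid chemistry tables.

Covalent-bond templates for the 20 standard residues (heavy atoms plus the
backbone amide hydrogen), donor/acceptor typing for hydrogen-bond detection,
van der Waals radii, and residue volumes.  Bonds are classified as *locked*
(peptide, double/partial-double, ring) or *rotatable*; the rigidity layer
turns locked bonds into body merges and rotatable bonds into hinges.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA1 = "ACDEFGHIKLMNPQRSTVWY"  # sorted 1-letter codes

# Residue volumes in cubic ångströms (Zamyatnin-style consensus values).
RESIDUE_VOLUME = {
    "G": 60.1, "A": 88.6, "S": 89.0,
    "C": 108.5, "D": 111.1, "P": 112.7, "N": 114.1, "T": 116.1,
    "E": 138.4, "V": 140.0, "Q": 143.8, "H": 153.2,
    "M": 162.9, "I": 166.7, "L": 166.7, "K": 168.6, "R": 173.4,
    "F": 189.9, "Y": 193.6, "W": 227.8,
}

VDW_RADIUS = {"C": 1.7, "S": 1.8}  # hydrophobic-tether elements only

# Side-chain bonds per residue: (atom_a, atom_b, locked).
# Backbone bonds (N-CA, CA-C rotatable; C-O, C-OXT and the inter-residue
# peptide C-N locked) are shared and added by `residue_bonds`.
_RING = True
_SC_BONDS = {
    "GLY": [],
    "ALA": [("CA", "CB", False)],
    "SER": [("CA", "CB", False), ("CB", "OG", False)],
    "CYS": [("CA", "CB", False), ("CB", "SG", False)],
    "THR": [("CA", "CB", False), ("CB", "OG1", False), ("CB", "CG2", False)],
    "VAL": [("CA", "CB", False), ("CB", "CG1", False), ("CB", "CG2", False)],
    "LEU": [("CA", "CB", False), ("CB", "CG", False),
            ("CG", "CD1", False), ("CG", "CD2", False)],
    "ILE": [("CA", "CB", False), ("CB", "CG1", False),
            ("CB", "CG2", False), ("CG1", "CD1", False)],
    "MET": [("CA", "CB", False), ("CB", "CG", False),
            ("CG", "SD", False), ("SD", "CE", False)],
    "PRO": [("CA", "CB", _RING), ("CB", "CG", _RING),
            ("CG", "CD", _RING), ("CD", "N", _RING)],
    "PHE": [("CA", "CB", False), ("CB", "CG", False),
            ("CG", "CD1", _RING), ("CD1", "CE1", _RING), ("CE1", "CZ", _RING),
            ("CZ", "CE2", _RING), ("CE2", "CD2", _RING), ("CD2", "CG", _RING)],
    "TYR": [("CA", "CB", False), ("CB", "CG", False),
            ("CG", "CD1", _RING), ("CD1", "CE1", _RING), ("CE1", "CZ", _RING),
            ("CZ", "CE2", _RING), ("CE2", "CD2", _RING), ("CD2", "CG", _RING),
            ("CZ", "OH", False)],
    "TRP": [("CA", "CB", False), ("CB", "CG", False),
            ("CG", "CD1", _RING), ("CD1", "NE1", _RING), ("NE1", "CE2", _RING),
            ("CE2", "CD2", _RING), ("CD2", "CG", _RING),
            ("CE2", "CZ2", _RING), ("CZ2", "CH2", _RING), ("CH2", "CZ3", _RING),
            ("CZ3", "CE3", _RING), ("CE3", "CD2", _RING)],
    "HIS": [("CA", "CB", False), ("CB", "CG", False),
            ("CG", "ND1", _RING), ("ND1", "CE1", _RING), ("CE1", "NE2", _RING),
            ("NE2", "CD2", _RING), ("CD2", "CG", _RING)],
    "ASP": [("CA", "CB", False), ("CB", "CG", False),
            ("CG", "OD1", True), ("CG", "OD2", True)],
    "GLU": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False),
            ("CD", "OE1", True), ("CD", "OE2", True)],
    "ASN": [("CA", "CB", False), ("CB", "CG", False),
            ("CG", "OD1", True), ("CG", "ND2", True)],
    "GLN": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False),
            ("CD", "OE1", True), ("CD", "NE2", True)],
    "LYS": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False),
            ("CD", "CE", False), ("CE", "NZ", False)],
    "ARG": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False),
            ("CD", "NE", False),
            ("NE", "CZ", True), ("CZ", "NH1", True), ("CZ", "NH2", True)],
}

_BACKBONE_BONDS = [("N", "CA", False), ("CA", "C", False),
                   ("C", "O", True), ("C", "OXT", True)]


def residue_bonds(resname: str) -> list[tuple[str, str, bool]]:
    """Intra-residue heavy-atom bond template (atom_a, atom_b, locked)."""
    if resname not in _SC_BONDS:
        raise KeyError(f"no bond template for residue {resname!r}")
    return _BACKBONE_BONDS + _SC_BONDS[resname]


# Heavy atoms that carry at least one (implicit or explicit) hydrogen and can
# donate. The backbone amide N of every residue except proline is a donor and
# is handled separately by name "N".
SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "CYS": {"SG"}, "TYR": {"OH"},
    "TRP": {"NE1"}, "HIS": {"ND1", "NE2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
}

# Lone-pair-bearing acceptors. Backbone carbonyl O / OXT accept for every
# residue; the protonated backbone amide N never does.
SIDECHAIN_ACCEPTORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "CYS": {"SG"}, "MET": {"SD"},
    "TYR": {"OH"}, "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"}, "GLN": {"OE1"}, "HIS": {"ND1", "NE2"},
}


def donor_atoms(resname: str) -> set[str]:
    donors = set(SIDECHAIN_DONORS.get(resname, ()))
    if resname != "PRO":
        donors.add("N")
    return donors


def acceptor_atoms(resname: str) -> set[str]:
    return {"O", "OXT"} | SIDECHAIN_ACCEPTORS.get(resname, set())
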