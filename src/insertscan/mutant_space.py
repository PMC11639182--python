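"""Enumeration and annotation of the exhaustive double-insertion mutant space.

A double-insertion mutant of an n-residue protein is identified by the
positions of the two inserted residues in the *elongated* (n+2)-long
sequence, 1-based with pos1 < pos2, plus the two inserted amino-acid types.
With the full 20-letter alphabet this gives C(n+2, 2) * 400 mutants, e.g.
451,200 for a 46-residue protein and 2,020,000 for a 99-residue one.

Back-mapping to wildtype insertion gaps: gap1 = pos1 - 1 and
gap2 = pos2 - 2, which makes each insertion's helix membership independent
of where the other insertion lands.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterator

from .chem import RESIDUE_VOLUME, STANDARD_AA1
from .structure_model import ProteinStructure, gap_in_helix

#: Volume-based amino-acid size classes (ranges in cubic ångströms):
#: very small 60-89, small 108-116, medium 138-153, large 162-173,
#: very large 189-227.
SIZE_CLASSES = {
    "VS": frozenset("GAS"),
    "S": frozenset("CDPNT"),
    "M": frozenset("EVQH"),
    "L": frozenset("MILKR"),
    "VL": frozenset("FYW"),
}
SIZE_ORDER = ("VS", "S", "M", "L", "VL")
_AA_TO_CLASS = {aa: label for label, members in SIZE_CLASSES.items()
                for aa in members}
HOMOGENEOUS_PAIR_LABELS = ("VSVS", "SS", "MM", "LL", "VLVL")


@dataclass(frozen=True)
class DoubleInsertion:
    """One point of the mutant space: two insertions into the elongated chain."""
    pos1: int
    pos2: int
    aa1: str
    aa2: str

    def __post_init__(self):
        if not 1 <= self.pos1 < self.pos2:
            raise ValueError("need 1 <= pos1 < pos2")
        for aa in (self.aa1, self.aa2):
            if aa not in _AA_TO_CLASS:
                raise ValueError(f"non-standard amino acid {aa!r}")

    @property
    def mutant_id(self) -> str:
        return f"{self.pos1}{self.aa1}_{self.pos2}{self.aa2}"

    @property
    def gaps(self) -> tuple[int, int]:
        """Wildtype insertion gaps (gap1, gap2) for the two insertions."""
        return self.pos1 - 1, self.pos2 - 2


def count_double_insertions(n_residues: int) -> int:
    """Size of the exhaustive double-insertion space: C(n+2, 2) * 400."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return comb(n_residues + 2, 2) * len(STANDARD_AA1) ** 2


def enumerate_double_insertions(n_residues: int,
                                alphabet: str = STANDARD_AA1,
                                ) -> Iterator[DoubleInsertion]:
    """Yield every double insertion once, in (pos1, pos2, aa1, aa2) order."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    alphabet = "".join(sorted(alphabet))
    n_elong = n_residues + 2
    for pos1 in range(1, n_elong):
        for pos2 in range(pos1 + 1, n_elong + 1):
            for aa1 in alphabet:
                for aa2 in alphabet:
                    yield DoubleInsertion(pos1, pos2, aa1, aa2)


def size_class_of(aa: str) -> str:
    """Volume size class (VS/S/M/L/VL) of a 1-letter amino-acid code."""
    try:
        return _AA_TO_CLASS[aa]
    except KeyError:
        raise ValueError(f"non-standard amino acid {aa!r}") from None


def pair_size_group(di: DoubleInsertion) -> str:
    """Unordered size-class pair label; homogeneous pairs get VSVS..VLVL."""
    return pair_size_group_of(di.aa1, di.aa2)


def pair_size_group_of(aa1: str, aa2: str) -> str:
    c1, c2 = size_class_of(aa1), size_class_of(aa2)
    if c1 == c2:
        return c1 * 2 if c1 in ("VS", "VL") else c1 + c1
    a, b = sorted((c1, c2), key=SIZE_ORDER.index)
    return f"{a}-{b}"


def residue_volume(aa: str) -> float:
    return RESIDUE_VOLUME[aa]


HELIX_GROUPS = ("I_XX", "I_XH", "I_HH")


def helix_group_of(di: DoubleInsertion, structure: ProteinStructure) -> str:
    """Helix group: I_XX, I_XH or I_HH by how many insertions fall in a helix.

    Elongated positions are mapped back to wildtype gaps before the helix
    test, so each insertion is classified independently of the other.
    """
    n = structure.n_residues
    if di.pos2 > n + 2:
        raise ValueError(f"pos2={di.pos2} beyond elongated length {n + 2}")
    g1, g2 = di.gaps
    hits = int(gap_in_helix(structure, g1)) + int(gap_in_helix(structure, g2))
    return HELIX_GROUPS[hits]
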