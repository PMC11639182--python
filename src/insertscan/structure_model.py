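"""Protein structure representation and PDB I/O.

A :class:`ProteinStructure` is a single chain of residues renumbered 1..n,
plus inclusive alpha-helix residue ranges taken from HELIX records.  An
*insertion gap* g in 0..n denotes the slot between residue g and residue
g+1 (0 = before the first residue, n = after the last); a gap lies "in a
helix" only when both flanking residues belong to the same helix range,
since that is the one placement that interrupts the helix.

PDB reading and writing are delegated to gemmi; only the first model and
first chain are kept, HETATM/water and non-standard residues are dropped.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .chem import THREE_TO_ONE

logger = logging.getLogger(__name__)


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into a ProteinStructure."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) in ångströms
    residue_index: int
    chain_id: str

    def __post_init__(self):
        if not self.element:
            raise ValueError("atom element must be non-empty")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)


@dataclass
class Residue:
    index: int  # 1-based sequence position after renumbering
    name: str   # 3-letter code
    atoms: list[Atom]

    def __post_init__(self):
        if self.index < 1:
            raise ValueError("residue index must be >= 1")
        if not self.atoms:
            raise ValueError(f"residue {self.index} has no atoms")
        self.is_standard = self.name in THREE_TO_ONE

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ProteinStructure:
    residues: list[Residue]
    helix_ranges: list[tuple[int, int]] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self):
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")
        n = self.n_residues
        for s, e in self.helix_ranges:
            if not (1 <= s <= e <= n):
                raise ValueError(f"helix range ({s},{e}) outside sequence 1..{n}")
        for (_, e1), (s2, _) in zip(sorted(self.helix_ranges),
                                    sorted(self.helix_ranges)[1:]):
            if s2 <= e1:
                raise ValueError("helix ranges must not overlap")
        serials = [a.serial for r in self.residues for a in r.atoms]
        if len(serials) != len(set(serials)):
            raise ValueError("atom serials must be unique within a structure")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Copy with a rigid-body transform applied to every atom."""
        rot = np.asarray(rotation, float)
        tr = np.asarray(translation, float)
        new_res = []
        for r in self.residues:
            new_atoms = [Atom(a.serial, a.name, a.element, rot @ a.coords + tr,
                              a.residue_index, a.chain_id) for a in r.atoms]
            new_res.append(Residue(r.index, r.name, new_atoms))
        return ProteinStructure(new_res, list(self.helix_ranges), self.source_id)


@dataclass(frozen=True)
class InsertionGap:
    """Gap g in 0..n: the slot between residue g and residue g+1."""
    gap: int

    def __post_init__(self):
        if self.gap < 0:
            raise ValueError("gap must be >= 0")


def gap_in_helix(structure: ProteinStructure, gap: InsertionGap | int) -> bool:
    """True iff residues g and g+1 both lie inside the same helix range.

    Terminal gaps (0 and n) are never inside a helix.
    """
    g = gap.gap if isinstance(gap, InsertionGap) else int(gap)
    n = structure.n_residues
    if not 0 <= g <= n:
        raise ValueError(f"gap {g} out of range 0..{n}")
    if g == 0 or g == n:
        return False
    return any(s <= g and g + 1 <= e for s, e in structure.helix_ranges)


def read_pdb(path, chain: str | None = None) -> ProteinStructure:
    """Parse a PDB file into a single-chain ProteinStructure.

    Takes the first model and (by default) its first chain; residues are
    renumbered 1..n in file order (insertion-code residues keep file order).
    HELIX records on the selected chain become ``helix_ranges``. HETATM,
    waters and residues without a bond template are excluded.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, FileNotFoundError) as exc:
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models / no ATOM records")
    if len(st) > 1:
        warnings.warn(f"{path}: {len(st)} models; keeping the first")
    model = st[0]
    chains = [ch for ch in model]
    if not chains:
        raise PDBParseError(f"{path}: no chains with ATOM records")
    if chain is not None:
        matches = [ch for ch in chains if ch.name == chain]
        if not matches:
            raise PDBParseError(f"{path}: chain {chain!r} not found")
        selected = matches[0]
    else:
        if len(chains) > 1:
            warnings.warn(f"{path}: {len(chains)} chains; keeping {chains[0].name!r}")
        selected = chains[0]

    residues: list[Residue] = []
    seqid_to_index: dict[tuple[int, str], int] = {}
    serial = 0
    for res in selected:
        if res.name == "HOH" or res.het_flag == "H" or res.name not in THREE_TO_ONE:
            logger.info("skipping non-standard residue %s %s", res.name, res.seqid)
            continue
        new_index = len(residues) + 1
        atoms = []
        for a in res:
            serial += 1
            pos = np.array([a.pos.x, a.pos.y, a.pos.z])
            if not np.all(np.isfinite(pos)):
                raise PDBParseError(
                    f"{path}: malformed coordinates for atom {a.name} in "
                    f"residue {res.name} {res.seqid}")
            atoms.append(Atom(serial, a.name, a.element.name.upper(), pos,
                              new_index, selected.name))
        if not atoms:
            continue
        residues.append(Residue(new_index, res.name, atoms))
        seqid_to_index[(res.seqid.num, res.seqid.icode.strip())] = new_index

    if not residues:
        raise PDBParseError(f"{path}: no ATOM records for standard residues")

    helix_ranges = []
    for h in st.helices:
        if h.start.chain_name != selected.name:
            continue
        start = seqid_to_index.get((h.start.res_id.seqid.num,
                                    h.start.res_id.seqid.icode.strip()))
        end = seqid_to_index.get((h.end.res_id.seqid.num,
                                  h.end.res_id.seqid.icode.strip()))
        if start is None or end is None:
            logger.warning("HELIX record %s-%s references missing residues; skipped",
                           h.start.res_id.seqid.num, h.end.res_id.seqid.num)
            continue
        if start > end:
            start, end = end, start
        helix_ranges.append((start, end))
    helix_ranges = _merge_overlaps(sorted(helix_ranges))

    source = st.name.strip().lower() if st.name else str(path)
    return ProteinStructure(residues, helix_ranges, source_id=source)


def _merge_overlaps(ranges: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in ranges:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return merged


def write_pdb(structure: ProteinStructure, path) -> None:
    """Write a ProteinStructure as a PDB file (ATOM + HELIX records)."""
    st = gemmi.Structure()
    st.name = structure.source_id or "insertscan"
    model = gemmi.Model("1")
    chain_id = structure.residues[0].atoms[0].chain_id or "A"
    chain = gemmi.Chain(chain_id)
    for r in structure.residues:
        gres = gemmi.Residue()
        gres.name = r.name
        gres.seqid = gemmi.SeqId(r.index, " ")
        gres.het_flag = "A"
        for a in r.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coords)
            ga.serial = a.serial
            ga.occ = 1.0
            ga.b_iso = 0.0
            gres.add_atom(ga)
        chain.add_residue(gres)
    model.add_chain(chain)
    st.add_model(model)
    for s, e in structure.helix_ranges:
        h = gemmi.Helix()
        h.start = gemmi.AtomAddress(chain_id, gemmi.SeqId(s, " "),
                                    structure.residues[s - 1].name, "")
        h.end = gemmi.AtomAddress(chain_id, gemmi.SeqId(e, " "),
                                  structure.residues[e - 1].name, "")
        h.pdb_helix_class = gemmi.Helix().pdb_helix_class.RAlpha
        h.length = e - s + 1
        st.helices.append(h)
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())


def structure_summary(structure: ProteinStructure) -> dict:
    """JSON-serializable summary: length, helices, atom count."""
    return {
        "source_id": structure.source_id,
        "n_residues": structure.n_residues,
        "n_atoms": len(structure.atoms),
        "helix_ranges": [list(r) for r in structure.helix_ranges],
        "sequence": structure.sequence,
    }


def write_summary(structure: ProteinStructure, path) -> None:
    with open(path, "w") as fh:
        json.dump(structure_summary(structure), fh, indent=2)
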