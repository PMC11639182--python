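"""Synthetic inputs for the pipeline.

Stands in for the structure-modelling stage that would otherwise supply
mutant coordinates: ideal-geometry polypeptides with known hydrogen-bond
content, reproducible random bar frameworks for exercising the pebble
game, and simulated per-mutant metric ensembles with planted group effects
expressed in standardized (Cohen's d) units.

The metric noise model is normal with truncation to each metric's range
(and rounding for the hydrogen-bond count).  Base means sit at least three
standard deviations from the range bounds so truncation bias is negligible
and a planted additive shift of ``delta`` standard deviations is recovered
as a Cohen's d of ``delta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .chem import STANDARD_AA1
from .ensemble_stats import MutantEnsemble
from .geometry import place_atom, torsion
from .mutant_space import HELIX_GROUPS, pair_size_group_of
from .rigidity import MAX_BARS, BodyBarHingeGraph
from .structure_model import Atom, ProteinStructure, Residue, gap_in_helix

# Ideal backbone internal coordinates (lengths in Å, angles in degrees).
BOND_LENGTHS = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329,
                "C-O": 1.231, "N-H": 1.010, "CA-CB": 1.521}
BOND_ANGLES = {"C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2,
               "CA-C-O": 120.5, "C-N-H": 119.5, "N-CA-CB": 110.4}
HELIX_PHI, HELIX_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -120.0, 120.0


def _build_polyalanine(n: int, phi: float, psi: float,
                       omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Backbone + CB + amide H coordinates for an n-residue poly-alanine."""
    if n < 1:
        raise ValueError("n must be >= 1")
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_LENGTHS["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(BOND_ANGLES["N-CA-C"])
    c0 = ca0 + BOND_LENGTHS["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n):
        prev = res[-1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"],
                         BOND_LENGTHS["C-N"], BOND_ANGLES["CA-C-N"], psi)
        ca_i = place_atom(prev["CA"], prev["C"], n_i,
                          BOND_LENGTHS["N-CA"], BOND_ANGLES["C-N-CA"], omega)
        c_i = place_atom(prev["C"], n_i, ca_i,
                         BOND_LENGTHS["CA-C"], BOND_ANGLES["N-CA-C"], phi)
        res.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, r in enumerate(res):
        if i + 1 < n:
            chi_o = torsion(r["N"], r["CA"], r["C"], res[i + 1]["N"]) + 180.0
        else:
            chi_o = psi + 180.0
        r["O"] = place_atom(r["N"], r["CA"], r["C"],
                            BOND_LENGTHS["C-O"], BOND_ANGLES["CA-C-O"], chi_o)
        r["CB"] = place_atom(r["C"], r["N"], r["CA"],
                             BOND_LENGTHS["CA-CB"], BOND_ANGLES["N-CA-CB"], 122.6)
        if i > 0:
            # amide H trans to the preceding carbonyl O across the peptide bond
            r["H"] = place_atom(res[i - 1]["O"], res[i - 1]["C"], r["N"],
                                BOND_LENGTHS["N-H"], BOND_ANGLES["C-N-H"], 180.0)
        else:
            r["H"] = place_atom(r["C"], r["CA"], r["N"],
                                BOND_LENGTHS["N-H"], BOND_ANGLES["C-N-H"], 180.0)
    return res


_ATOM_ORDER = [("N", "N"), ("H", "H"), ("CA", "C"), ("CB", "C"),
               ("C", "C"), ("O", "O")]


def _to_structure(coords: list[dict[str, np.ndarray]],
                  helix_ranges: list[tuple[int, int]],
                  source_id: str) -> ProteinStructure:
    residues = []
    serial = 0
    for i, rc in enumerate(coords, start=1):
        atoms = []
        for name, element in _ATOM_ORDER:
            serial += 1
            atoms.append(Atom(serial, name, element, rc[name], i, "A"))
        residues.append(Residue(i, "ALA", atoms))
    return ProteinStructure(residues, helix_ranges, source_id=source_id)


def ideal_helix_structure(n: int) -> ProteinStructure:
    """Poly-alanine ideal alpha helix (phi=-57, psi=-47), annotated 1..n.

    Backbone amide hydrogens are placed analytically, so the geometric
    detector finds exactly the i -> i-4 backbone hydrogen bonds
    (n - 4 of them for n >= 5).
    """
    coords = _build_polyalanine(n, HELIX_PHI, HELIX_PSI)
    helix = [(1, n)] if n >= 2 else []
    return _to_structure(coords, helix, f"ideal_helix_{n}")


def extended_chain_structure(n: int) -> ProteinStructure:
    """Poly-alanine extended chain (phi=-120, psi=120); no hydrogen bonds."""
    coords = _build_polyalanine(n, EXTENDED_PHI, EXTENDED_PSI)
    return _to_structure(coords, [], f"extended_chain_{n}")


def random_framework(n_bodies: int, bar_spec, seed: int) -> BodyBarHingeGraph:
    """Reproducible random body-bar multigraph for pebble-game exercises.

    ``bar_spec`` is either an integer number of bars to scatter over random
    body pairs (per-pair totals capped at 6) or an explicit iterable of
    (u, v, bars) records.
    """
    if n_bodies < 1:
        raise ValueError("n_bodies must be >= 1")
    rng = np.random.default_rng(seed)
    edges: dict[tuple[int, int], int] = {}
    if isinstance(bar_spec, (int, np.integer)):
        placed = 0
        attempts = 0
        while placed < bar_spec and attempts < 50 * max(1, int(bar_spec)):
            attempts += 1
            if n_bodies < 2:
                break
            u, v = sorted(rng.choice(n_bodies, size=2, replace=False))
            key = (int(u), int(v))
            if edges.get(key, 0) >= MAX_BARS:
                continue
            edges[key] = edges.get(key, 0) + 1
            placed += 1
    else:
        for u, v, bars in bar_spec:
            if u == v:
                raise ValueError("self-edge in bar_spec")
            key = (min(u, v), max(u, v))
            edges[key] = min(MAX_BARS, edges.get(key, 0) + int(bars))
    atom_map = {i: i for i in range(n_bodies)}
    return BodyBarHingeGraph(bodies=list(range(n_bodies)), edges=edges,
                             atom_map=atom_map)


@dataclass(frozen=True)
class PlantedEffect:
    """Additive mean shift (in sd units) on one metric for a mutant subset.

    ``where`` is either an annotation (column, value) pair, e.g.
    ("helix_group", "I_HH"), or a callable DataFrame -> boolean mask.
    """
    where: tuple[str, str] | Callable[[pd.DataFrame], np.ndarray]
    metric: str
    shift_sd: float


@dataclass
class SyntheticEnsembleConfig:
    """Study conditions for a simulated mutant metric ensemble.

    Defaults emulate a small-protein run: hydrogen-bond counts around a
    mean of 5.5 (the crambin-scale mutant average) and mid-range rigidity
    scores, with noise kept >= 3 sd away from the metric bounds.
    """
    metrics: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "hbc": (5.5, 1.5),
        "cce": (0.55, 0.08),
        "rop": (0.45, 0.08),
    })
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    seed: int = 0
    coverage: float = 1.0

    def __post_init__(self):
        for name, (_, sd) in self.metrics.items():
            if sd <= 0:
                raise ValueError(f"metric {name!r} sd must be > 0")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must be in (0, 1]")


def simulate_metric_ensemble(config: SyntheticEnsembleConfig,
                             structure: ProteinStructure) -> MutantEnsemble:
    """Simulate per-mutant metrics over the double-insertion space.

    Enumerates (or samples, per ``coverage``) the space for the structure's
    length, annotates every mutant with gaps, helix group and size group,
    and draws each metric from a normal with the configured base mean/sd
    plus any planted shifts, then truncates/rounds to the metric's range.
    Fully reproducible from the seed.
    """
    n = structure.n_residues
    rng = np.random.default_rng(config.seed)

    iu, ju = np.triu_indices(n + 2, k=1)
    pos1_pairs, pos2_pairs = iu + 1, ju + 1
    n_pos = len(pos1_pairs)
    aa = np.array(list(STANDARD_AA1))
    n_aa = len(aa)
    aa1_idx = np.repeat(np.arange(n_aa), n_aa)
    aa2_idx = np.tile(np.arange(n_aa), n_aa)

    pos1 = np.repeat(pos1_pairs, n_aa * n_aa)
    pos2 = np.repeat(pos2_pairs, n_aa * n_aa)
    a1 = np.tile(aa1_idx, n_pos)
    a2 = np.tile(aa2_idx, n_pos)

    if config.coverage < 1.0:
        total = len(pos1)
        keep = round(total * config.coverage)
        sel = np.sort(rng.choice(total, size=keep, replace=False))
        pos1, pos2, a1, a2 = pos1[sel], pos2[sel], a1[sel], a2[sel]

    gap1 = pos1 - 1
    gap2 = pos2 - 2
    in_helix = np.array([gap_in_helix(structure, g) for g in range(n + 1)])
    hits = in_helix[gap1].astype(int) + in_helix[gap2].astype(int)
    helix_group = np.array(HELIX_GROUPS)[hits]

    pair_label = np.empty((n_aa, n_aa), dtype=object)
    for i, x in enumerate(aa):
        for j, y in enumerate(aa):
            pair_label[i, j] = pair_size_group_of(x, y)
    size_group = pair_label[a1, a2]

    df = pd.DataFrame({
        "pos1": pos1, "pos2": pos2,
        "aa1": aa[a1], "aa2": aa[a2],
        "gap1": gap1, "gap2": gap2,
        "helix_group": helix_group,
        "size_group": size_group,
    })
    df["mutant_id"] = (df["pos1"].astype(str) + df["aa1"] + "_"
                       + df["pos2"].astype(str) + df["aa2"])

    for metric in sorted(config.metrics):
        mean, sd = config.metrics[metric]
        values = mean + sd * rng.standard_normal(len(df))
        for eff in config.planted_effects:
            if eff.metric != metric:
                continue
            if callable(eff.where):
                mask = np.asarray(eff.where(df), bool)
            else:
                col, val = eff.where
                mask = (df[col] == val).to_numpy()
            if not mask.any():
                warnings.warn(f"planted effect on {eff.where} matches no mutants")
            values = values + np.where(mask, eff.shift_sd * sd, 0.0)
        if metric == "hbc":
            values = np.maximum(np.rint(values), 0).astype(int)
        elif metric == "cce":
            values = np.clip(values, 0.0, 1.0)
        elif metric == "rop":
            values = np.clip(values, 1e-9, 1.0)
        df[metric] = values

    cols = ["mutant_id", "hbc", "cce", "rop", "pos1", "pos2", "aa1", "aa2",
            "gap1", "gap2", "helix_group", "size_group"]
    return MutantEnsemble(df[cols])
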