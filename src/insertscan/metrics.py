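"""Per-structure metrics: hydrogen-bond count, cluster configuration
entropy (CCE) and rigidity order parameter (ROP).

Both CCE and ROP are computed from the atom-level rigid-cluster size
distribution.  CCE is the Shannon entropy of that distribution normalized
by ln(N), so it ranges over [0, 1]: 0 for a single rigid cluster (fully
rigid), 1 for all-singleton clusters (fully flexible).  ROP is the fraction
of atoms in the largest rigid cluster, in (0, 1]: higher means a larger
dominant rigid core and hence a more stable structure.  The two agree at
the extremes: ROP = 1 exactly when CCE = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

from .interactions import DEFAULT_CONFIG, InteractionConfig, all_interactions, hbond_count
from .rigidity import build_mechanical_model, pebble_game, rigid_clusters_atoms
from .structure_model import ProteinStructure


@dataclass(frozen=True)
class MetricRecord:
    mutant_id: str
    hbc: int
    cce: float
    rop: float
    n_atoms: int

    def __post_init__(self):
        if self.hbc < 0 or self.n_atoms < 1:
            raise ValueError("hbc must be >= 0 and n_atoms >= 1")
        if not 0.0 <= self.cce <= 1.0:
            raise ValueError("cce out of [0, 1]")
        if not 0.0 < self.rop <= 1.0:
            raise ValueError("rop out of (0, 1]")


def _check_sizes(cluster_sizes) -> list[int]:
    sizes = [int(s) for s in cluster_sizes]
    if not sizes or any(s <= 0 for s in sizes):
        raise ValueError("cluster sizes must be positive and non-empty")
    return sizes


def cce(cluster_sizes) -> float:
    """Cluster configuration entropy: -sum (s/N) ln(s/N) / ln(N), in [0,1]."""
    sizes = _check_sizes(cluster_sizes)
    n = sum(sizes)
    if n == 1 or len(sizes) == 1:
        return 0.0
    h = -sum((s / n) * log(s / n) for s in sizes)
    return h / log(n)


def rop(cluster_sizes) -> float:
    """Rigidity order parameter: largest cluster fraction max(s)/N, in (0,1]."""
    sizes = _check_sizes(cluster_sizes)
    return max(sizes) / sum(sizes)


def metric_record(structure: ProteinStructure,
                  mutant_id: str = "",
                  config: InteractionConfig = DEFAULT_CONFIG) -> MetricRecord:
    """Full pipeline for one structure: interactions -> rigidity -> metrics."""
    inters = all_interactions(structure, config)
    graph = build_mechanical_model(structure, inters)
    decomp = pebble_game(graph)
    sizes = [len(s) for s in rigid_clusters_atoms(decomp, graph)]
    return MetricRecord(
        mutant_id=mutant_id or structure.source_id,
        hbc=sum(1 for i in inters if i.kind == "hbond"),
        cce=cce(sizes),
        rop=rop(sizes),
        n_atoms=sum(sizes),
    )
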