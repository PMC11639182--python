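"""Body-bar-hinge mechanical model and (6,6) pebble game.

Atoms are rigid bodies; locked covalent bonds (peptide, double/partial
double, rings, hydrogen attachments) merge atoms into larger bodies.
Rotatable covalent bonds are hinges (5 bars), hydrogen bonds contribute 5
bars and hydrophobic tethers 2, following the body-bar-hinge conventions of
combinatorial rigidity (a generic bar removes one relative degree of
freedom; six generic bars lock two bodies together, matching the
Tay-Whiteley correspondence for 3D multigraphs).

The (6,6) pebble game decides which bars are independent: each body starts
with 6 pebbles (its 6 rigid-body degrees of freedom) and a bar is accepted
only if 7 pebbles can be gathered on its two endpoints, after which one
pebble is consumed and the bar oriented.  Rigid clusters are maximal body
sets with zero internal relative freedom, detected pairwise: two bodies are
mutually rigid exactly when no pebble rearrangement can free more than 6
pebbles on the pair.  With fixed lexicographic edge order and sorted
depth-first searches the decomposition is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .interactions import Interaction, covalent_bonds
from .structure_model import ProteinStructure

MAX_BARS = 6
PEBBLES_PER_BODY = 6


@dataclass
class BodyBarHingeGraph:
    """Multigraph of rigid bodies joined by bars.

    ``bodies`` are integer ids; ``edges`` maps an ordered body pair
    (u < v) to a bar count in 1..6; ``atom_map`` sends each atom serial to
    its body.  Parallel constraints between one body pair are summed and
    capped at 6 bars (6 bars already lock the pair).
    """
    bodies: list[int]
    edges: dict[tuple[int, int], int]
    atom_map: dict[int, int] = field(default_factory=dict)
    edge_kinds: dict[tuple[int, int], tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        bodyset = set(self.bodies)
        for (u, v), bars in self.edges.items():
            if u == v:
                raise ValueError("self-edge after body merging")
            if not (u in bodyset and v in bodyset):
                raise ValueError(f"edge ({u},{v}) references unknown body")
            if not 1 <= bars <= MAX_BARS:
                raise ValueError(f"edge ({u},{v}) has {bars} bars (must be 1..6)")
        for serial, b in self.atom_map.items():
            if b not in bodyset:
                raise ValueError(f"atom {serial} mapped to unknown body {b}")

    @property
    def total_bars(self) -> int:
        return sum(self.edges.values())

    def atoms_of_body(self, body: int) -> list[int]:
        return sorted(s for s, b in self.atom_map.items() if b == body)


@dataclass
class RigidClusterDecomposition:
    """Partition of bodies into rigid clusters plus pebble-game counts."""
    clusters: list[list[int]]          # body ids, each cluster sorted
    independent_edges: int
    redundant_edges: int
    internal_dof: int                  # 6*|bodies| - independent bars

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra

    def groups(self) -> list[list]:
        out: dict = {}
        for x in self.parent:
            out.setdefault(self.find(x), []).append(x)
        return [sorted(v) for v in out.values()]


def build_mechanical_model(structure: ProteinStructure,
                           interactions: list[Interaction] | None = None,
                           ) -> BodyBarHingeGraph:
    """Assemble the body-bar-hinge multigraph for a structure.

    When ``interactions`` is None the covalent topology is inferred from
    residue templates; otherwise the given list (which may mix covalent,
    hbond and hydrophobic interactions) is used as-is, with covalent
    template bonds always included.
    """
    atoms = structure.atoms
    serials = [a.serial for a in atoms]
    serialset = set(serials)
    cov = covalent_bonds(structure)
    extra = [i for i in (interactions or []) if i.kind != "covalent"]
    for inter in extra:
        for a in (inter.atom_a, inter.atom_b):
            if a.serial not in serialset:
                raise ValueError(f"interaction references unknown atom {a.serial}")

    uf = _UnionFind(serials)
    for b in cov:
        if b.locked or b.bars >= MAX_BARS:
            uf.union(b.atom_a.serial, b.atom_b.serial)

    # Body ids: rank of the smallest atom serial in each merged set.
    rep_of = {s: uf.find(s) for s in serials}
    reps = sorted(set(rep_of.values()))
    body_id = {rep: i for i, rep in enumerate(reps)}
    atom_map = {s: body_id[rep_of[s]] for s in serials}

    edges: dict[tuple[int, int], int] = {}
    kinds: dict[tuple[int, int], list[str]] = {}
    for inter in cov + extra:
        u = atom_map[inter.atom_a.serial]
        v = atom_map[inter.atom_b.serial]
        if u == v:
            continue  # constraint internal to one body
        key = (u, v) if u < v else (v, u)
        edges[key] = min(MAX_BARS, edges.get(key, 0) + inter.bars)
        kinds.setdefault(key, []).append(inter.kind)

    return BodyBarHingeGraph(bodies=list(range(len(reps))),
                             edges=edges,
                             atom_map=atom_map,
                             edge_kinds={k: tuple(v) for k, v in kinds.items()})


class PebbleGame6:
    """(6,6) pebble game on a body-bar multigraph.

    Maintains a directed multigraph of accepted bars; ``pebbles[v]`` is the
    free-pebble count at body v.  Searches are depth-first over sorted
    adjacency, so outcomes are deterministic for a fixed insertion order.
    """

    def __init__(self, bodies):
        self.pebbles = {v: PEBBLES_PER_BODY for v in bodies}
        self.out: dict[int, dict[int, int]] = {v: {} for v in bodies}
        self.independent = 0
        self.redundant = 0

    def _reversal_path(self, root: int, forbidden: frozenset[int]):
        """DFS from root for a body outside ``forbidden`` with a free pebble."""
        stack = [root]
        prev: dict[int, int] = {root: -1}
        while stack:
            u = stack.pop()
            if u != root and u not in forbidden and self.pebbles[u] > 0:
                path = [u]
                while path[-1] != root:
                    path.append(prev[path[-1]])
                return path  # from pebble holder back to root
            for w in sorted(self.out[u], reverse=True):
                if w not in prev:
                    prev[w] = u
                    stack.append(w)
        return None

    def _move_pebble_to(self, root: int, other: int) -> bool:
        """Free one pebble onto ``root`` without taking it from ``other``."""
        path = self._reversal_path(root, frozenset((root, other)))
        if path is None:
            return False
        holder = path[0]
        self.pebbles[holder] -= 1
        self.pebbles[root] += 1
        for child, parent in zip(path, path[1:]):
            # reverse edge parent -> child
            self.out[parent][child] -= 1
            if self.out[parent][child] == 0:
                del self.out[parent][child]
            self.out[child][parent] = self.out[child].get(parent, 0) + 1
        return True

    def collect(self, u: int, v: int, target: int) -> int:
        """Gather up to ``target`` free pebbles onto bodies u and v."""
        while self.pebbles[u] + self.pebbles[v] < target:
            if self.pebbles[u] < PEBBLES_PER_BODY and self._move_pebble_to(u, v):
                continue
            if self.pebbles[v] < PEBBLES_PER_BODY and self._move_pebble_to(v, u):
                continue
            break
        return self.pebbles[u] + self.pebbles[v]

    def add_bar(self, u: int, v: int) -> bool:
        """Insert one bar; True if independent (accepted), False if redundant."""
        if self.collect(u, v, PEBBLES_PER_BODY + 1) >= PEBBLES_PER_BODY + 1:
            if self.pebbles[u] == 0:
                u, v = v, u
            self.pebbles[u] -= 1
            self.out[u][v] = self.out[u].get(v, 0) + 1
            self.independent += 1
            return True
        self.redundant += 1
        return False

    def mutually_rigid(self, u: int, v: int) -> bool:
        """True iff bodies u and v have zero relative degrees of freedom."""
        return self.collect(u, v, PEBBLES_PER_BODY + 1) < PEBBLES_PER_BODY + 1


def pebble_game(graph: BodyBarHingeGraph,
                edge_order: list[tuple[int, int]] | None = None,
                ) -> RigidClusterDecomposition:
    """Run the (6,6) pebble game and extract rigid clusters.

    Bars are inserted in lexicographic (u, v) edge order by default;
    ``edge_order`` overrides it (the decomposition and the independent-bar
    count are order-invariant, only useful for diagnostics).  Mutual
    rigidity of body pairs is an equivalence (two clusters sharing a body
    coincide), so clusters are grown with a union-find over pairwise
    pebble queries.
    """
    game = PebbleGame6(graph.bodies)
    order = edge_order if edge_order is not None else sorted(graph.edges)
    for (u, v) in order:
        for _ in range(graph.edges[(u, v) if (u, v) in graph.edges else (v, u)]):
            game.add_bar(u, v)

    uf = _UnionFind(graph.bodies)
    bodies = sorted(graph.bodies)
    for i, u in enumerate(bodies):
        for v in bodies[i + 1:]:
            if uf.find(u) == uf.find(v):
                continue
            # only bodies connected by some path can be mutually rigid
            if game.mutually_rigid(u, v):
                uf.union(u, v)
    clusters = sorted(uf.groups(), key=lambda c: (-len(c), c))
    return RigidClusterDecomposition(
        clusters=clusters,
        independent_edges=game.independent,
        redundant_edges=game.redundant,
        internal_dof=PEBBLES_PER_BODY * len(graph.bodies) - game.independent,
    )


def rigid_clusters_atoms(decomp: RigidClusterDecomposition,
                         graph: BodyBarHingeGraph) -> list[set[int]]:
    """Expand body clusters to atom-serial sets, largest first."""
    atoms_by_body: dict[int, list[int]] = {}
    for serial, b in graph.atom_map.items():
        atoms_by_body.setdefault(b, []).append(serial)
    missing = [b for c in decomp.clusters for b in c if b not in atoms_by_body]
    sets = []
    for cluster in decomp.clusters:
        atoms = {s for b in cluster for s in atoms_by_body.get(b, ())}
        if atoms:
            sets.append(atoms)
    if sum(len(s) for s in sets) != len(graph.atom_map) and not missing:
        raise ValueError("decomposition does not match graph atom map")
    sets.sort(key=lambda s: (-len(s), min(s)))
    return sets


def rigidity_summary(structure: ProteinStructure,
                     interactions: list[Interaction] | None = None) -> dict:
    """Cluster sizes, degrees of freedom and redundancy for one structure."""
    graph = build_mechanical_model(structure, interactions)
    decomp = pebble_game(graph)
    atom_sets = rigid_clusters_atoms(decomp, graph)
    return {
        "n_bodies": len(graph.bodies),
        "n_bars": graph.total_bars,
        "independent_edges": decomp.independent_edges,
        "redundant_edges": decomp.redundant_edges,
        "internal_dof": decomp.internal_dof,
        "cluster_sizes_atoms": [len(s) for s in atom_sets],
    }
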