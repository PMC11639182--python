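import numpy as np
import pytest

from insertscan.rigidity import (BodyBarHingeGraph, PebbleGame6,
                                 build_mechanical_model, pebble_game,
                                 rigid_clusters_atoms)
from insertscan.synthetic_data import random_framework
from conftest import make_structure
from oracles import brute_force_rigid_pairs, rigidity_matrix_rank


def test_single_free_body():
    g = BodyBarHingeGraph(bodies=[0], edges={}, atom_map={1: 0})
    d = pebble_game(g)
    assert d.clusters == [[0]]
    assert d.internal_dof == 6
    assert d.redundant_edges == 0


def test_two_bodies_six_bars_form_one_cluster():
    g = BodyBarHingeGraph(bodies=[0, 1], edges={(0, 1): 6},
                          atom_map={1: 0, 2: 1})
    d = pebble_game(g)
    assert d.clusters == [[0, 1]]
    assert d.independent_edges == 6
    assert d.internal_dof == 6  # only the shared rigid-body motion remains


def test_seventh_bar_between_two_bodies_is_redundant():
    game = PebbleGame6([0, 1])
    results = [game.add_bar(0, 1) for _ in range(7)]
    assert results == [True] * 6 + [False]
    assert game.independent == 6 and game.redundant == 1
    assert game.mutually_rigid(0, 1)


def test_five_bar_hinge_leaves_one_dof():
    g = BodyBarHingeGraph(bodies=[0, 1], edges={(0, 1): 5},
                          atom_map={1: 0, 2: 1})
    d = pebble_game(g)
    assert d.independent_edges == 5
    assert d.clusters == [[0], [1]]  # one relative rotation left


def test_locked_bond_merges_bodies():
    """A two-residue peptide: the C(i), O(i), N(i+1) atoms form one body."""
    res = [("GLY", [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
                    ("C", "C", (2.0, 1.4, 0)), ("O", "O", (3.2, 1.5, 0))]),
           ("GLY", [("N", "N", (1.4, 2.4, 0)), ("CA", "C", (1.8, 3.8, 0)),
                    ("C", "C", (3.2, 4.3, 0)), ("O", "O", (4.2, 3.6, 0))])]
    st = make_structure(res)
    graph = build_mechanical_model(st)
    serial_of = {(a.residue_index, a.name): a.serial for a in st.atoms}
    b = graph.atom_map
    assert b[serial_of[(1, "C")]] == b[serial_of[(1, "O")]] == b[serial_of[(2, "N")]]
    assert b[serial_of[(1, "N")]] != b[serial_of[(1, "CA")]]


def test_single_glycine_model():
    """One glycine: bodies {N}, {CA}, {C,O} joined by two hinges."""
    st = make_structure([("GLY", [("N", "N", (0, 0, 0)),
                                  ("CA", "C", (1.5, 0, 0)),
                                  ("C", "C", (2.0, 1.4, 0)),
                                  ("O", "O", (3.2, 1.5, 0))])])
    graph = build_mechanical_model(st)
    assert len(graph.bodies) == 3
    assert sorted(graph.edges.values()) == [5, 5]
    d = pebble_game(graph)
    assert d.internal_dof == 18 - 10
    assert len(d.clusters) == 3


def test_parallel_bars_capped_at_six():
    g = random_framework(2, [(0, 1, 5), (0, 1, 5)], seed=0)
    assert g.edges == {(0, 1): 6}


def test_pebble_count_conservation():
    for seed in range(25):
        rng = np.random.default_rng(seed)
        g = random_framework(int(rng.integers(2, 9)), int(rng.integers(0, 31)),
                             seed=seed)
        d = pebble_game(g)
        assert d.independent_edges + d.redundant_edges == g.total_bars
        assert d.internal_dof >= 6


def test_matches_rank_oracle_small_sample():
    for seed in range(40):
        rng = np.random.default_rng(seed)
        g = random_framework(int(rng.integers(1, 9)), int(rng.integers(0, 31)),
                             seed=seed + 1000)
        d = pebble_game(g)
        assert d.independent_edges == rigidity_matrix_rank(g, seed=seed)


def test_clusters_match_brute_force_pairs():
    for seed in range(25):
        rng = np.random.default_rng(seed)
        g = random_framework(int(rng.integers(2, 8)), int(rng.integers(0, 26)),
                             seed=seed + 500)
        d = pebble_game(g)
        expected = brute_force_rigid_pairs(g, seed=seed)
        got = {frozenset((u, v)) for c in d.clusters
               for i, u in enumerate(c) for v in c[i + 1:]}
        assert got == expected


def test_adding_a_bar_never_splits_a_cluster():
    for seed in range(15):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        g = random_framework(n, int(rng.integers(3, 25)), seed=seed + 99)
        before = pebble_game(g).clusters
        u, v = sorted(rng.choice(n, 2, replace=False))
        edges = dict(g.edges)
        edges[(int(u), int(v))] = min(6, edges.get((int(u), int(v)), 0) + 1)
        g2 = BodyBarHingeGraph(g.bodies, edges, dict(g.atom_map))
        after = pebble_game(g2).clusters
        cluster_of = {b: i for i, c in enumerate(after) for b in c}
        for c in before:  # each old cluster sits inside one new cluster
            assert len({cluster_of[b] for b in c}) == 1


def test_decomposition_invariant_to_edge_order():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        g = random_framework(int(rng.integers(2, 9)), int(rng.integers(5, 31)),
                             seed=seed + 77)
        ref = pebble_game(g)
        order = list(g.edges)
        rng.shuffle(order)
        alt = pebble_game(g, edge_order=order)
        assert alt.clusters == ref.clusters
        assert alt.independent_edges == ref.independent_edges


def test_atom_cluster_expansion_partitions_atoms(helix12):
    from insertscan.interactions import all_interactions
    graph = build_mechanical_model(helix12, all_interactions(helix12))
    decomp = pebble_game(graph)
    sets = rigid_clusters_atoms(decomp, graph)
    sizes = [len(s) for s in sets]
    assert sizes == sorted(sizes, reverse=True)
    assert sum(sizes) == len(helix12.atoms)
    union = set().union(*sets)
    assert union == {a.serial for a in helix12.atoms}


def test_interaction_with_unknown_atom_rejected(helix12):
    from insertscan.interactions import Interaction
    from insertscan.structure_model import Atom
    ghost = Atom(9999, "X", "C", np.zeros(3), 1, "A")
    bad = Interaction("hbond", helix12.atoms[0], ghost, bars=5)
    with pytest.raises(ValueError):
        build_mechanical_model(helix12, [bad])
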