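"""Independent oracles used by the test suite.

The generic body-bar rigidity-matrix rank is the linear-algebra counterpart
of the combinatorial pebble game: place each body at random, attach each
bar at random points on its two endpoint bodies, and build one constraint
row per bar; for generic placements the matrix rank equals the number of
independent bars.  Taking the max over a few random placements guards
against accidental non-generic configurations.
"""

from __future__ import annotations

import numpy as np

from insertscan.rigidity import BodyBarHingeGraph


def _bar_row(n_bodies: int, u: int, v: int, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Constraint row for a bar from point pa on body u to point pb on body v.

    Body velocities are screws (v, w); the bar preserves the distance
    between its endpoints: (v_u + w_u x pa - v_v - w_v x pb) . (pa - pb) = 0.
    """
    row = np.zeros(6 * n_bodies)
    e = pa - pb
    row[6 * u:6 * u + 3] = e
    row[6 * u + 3:6 * u + 6] = np.cross(pa, e)
    row[6 * v:6 * v + 3] = -e
    row[6 * v + 3:6 * v + 6] = -np.cross(pb, e)
    return row


def rigidity_matrix_rank(graph: BodyBarHingeGraph, seed: int = 0,
                         n_placements: int = 3) -> int:
    """Generic rank of the body-bar rigidity matrix (max over placements)."""
    n = len(graph.bodies)
    index = {b: i for i, b in enumerate(sorted(graph.bodies))}
    best = 0
    for trial in range(n_placements):
        rng = np.random.default_rng(seed * 1000 + trial)
        centers = rng.uniform(-10, 10, size=(n, 3))
        rows = []
        for (u, v), bars in sorted(graph.edges.items()):
            iu, iv = index[u], index[v]
            for _ in range(bars):
                pa = centers[iu] + rng.uniform(-1, 1, 3)
                pb = centers[iv] + rng.uniform(-1, 1, 3)
                rows.append(_bar_row(n, iu, iv, pa, pb))
        if not rows:
            return 0
        rank = np.linalg.matrix_rank(np.array(rows), tol=1e-8)
        best = max(best, int(rank))
    return best


def brute_force_rigid_pairs(graph: BodyBarHingeGraph, seed: int = 0) -> set[frozenset]:
    """Mutually rigid body pairs via the rigidity matrix null space.

    A pair (u, v) is rigid iff appending 6 generic bars between u and v
    raises the rank by 0 (their relative motion is already fully blocked).
    """
    n = len(graph.bodies)
    index = {b: i for i, b in enumerate(sorted(graph.bodies))}
    rng = np.random.default_rng(seed + 7)
    centers = rng.uniform(-10, 10, size=(n, 3))
    base_rows = []
    for (u, v), bars in sorted(graph.edges.items()):
        iu, iv = index[u], index[v]
        for _ in range(bars):
            pa = centers[iu] + rng.uniform(-1, 1, 3)
            pb = centers[iv] + rng.uniform(-1, 1, 3)
            base_rows.append(_bar_row(n, iu, iv, pa, pb))
    base = np.array(base_rows) if base_rows else np.zeros((0, 6 * n))
    base_rank = int(np.linalg.matrix_rank(base, tol=1e-8)) if base_rows else 0

    rigid = set()
    bodies = sorted(graph.bodies)
    for i, u in enumerate(bodies):
        for v in bodies[i + 1:]:
            iu, iv = index[u], index[v]
            extra = [_bar_row(n, iu, iv,
                              centers[iu] + rng.uniform(-1, 1, 3),
                              centers[iv] + rng.uniform(-1, 1, 3))
                     for _ in range(6)]
            aug = np.vstack([base, extra])
            if int(np.linalg.matrix_rank(aug, tol=1e-8)) == base_rank + 0:
                rigid.add(frozenset((u, v)))
    return rigid
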