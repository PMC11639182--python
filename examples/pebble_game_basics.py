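"""The (6,6) pebble game on small body-bar frameworks.

Each rigid body carries 6 degrees of freedom (pebbles); a bar between two
bodies is independent when 7 pebbles can be gathered on its endpoints, and
6 independent bars lock a pair into one rigid cluster.  A 7th parallel bar
is redundant.
"""

from insertscan import pebble_game
from insertscan.synthetic_data import random_framework

# two bodies, six bars: rigid, no redundancy
g = random_framework(2, [(0, 1, 6)], seed=0)
d = pebble_game(g)
print(f"2 bodies / 6 bars: clusters={d.clusters}, "
      f"independent={d.independent_edges}, redundant={d.redundant_edges}, "
      f"internal DOF={d.internal_dof}")

# a chain of hinges (5 bars each) leaves one twist DOF per link
g = random_framework(4, [(0, 1, 5), (1, 2, 5), (2, 3, 5)], seed=0)
d = pebble_game(g)
print(f"hinge chain of 4 bodies: clusters={d.clusters}, "
      f"internal DOF={d.internal_dof} (6 rigid-body + 3 hinge twists)")

# a random dense framework: count conservation holds by construction
g = random_framework(6, 30, seed=42)
d = pebble_game(g)
print(f"random 6-body / {g.total_bars}-bar framework: "
      f"{d.independent_edges} independent + {d.redundant_edges} redundant bars, "
      f"{len(d.clusters)} rigid clusters")
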