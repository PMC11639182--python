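"""Hydrogen bonds and rigidity metrics for ideal-geometry chains.

An ideal alpha helix is held together by backbone i -> i-4 hydrogen bonds
(8 of them for 12 residues), which the rigidity analysis turns into one
dominant rigid cluster: low cluster configuration entropy (CCE) and high
rigidity order parameter (ROP).  The same chain built with extended
dihedrals has no hydrogen bonds and decomposes into many small clusters.
"""

from insertscan import hbond_count, metric_record
from insertscan.interactions import all_interactions
from insertscan.rigidity import rigidity_summary
from insertscan.synthetic_data import (extended_chain_structure,
                                       ideal_helix_structure)

for build in (ideal_helix_structure, extended_chain_structure):
    st = build(12)
    r = metric_record(st)
    summary = rigidity_summary(st, all_interactions(st))
    print(f"{st.source_id}:")
    print(f"  hydrogen bonds: {r.hbc}")
    print(f"  rigid cluster sizes (atoms): {summary['cluster_sizes_atoms']}")
    print(f"  CCE = {r.cce:.3f}  (0 = fully rigid, 1 = fully fragmented)")
    print(f"  ROP = {r.rop:.3f}  (fraction of atoms in the largest cluster)")
    print()

print("The helix is stiffer on both metrics: hydrogen bonds act as 5-bar")
print("constraints that fuse the hinge chain into one large rigid cluster.")
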