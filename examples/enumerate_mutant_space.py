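"""Enumerate and annotate the exhaustive double-insertion mutant space.

For an n-residue protein there are C(n+2, 2) position pairs in the
elongated chain and 400 ordered residue pairs, so the space has
C(n+2, 2) * 400 mutants.  For the five study-scale lengths this prints
451,200 up to 3,200,400 mutants.
"""

from itertools import islice

from insertscan import count_double_insertions, enumerate_double_insertions
from insertscan.mutant_space import helix_group_of, pair_size_group
from insertscan.synthetic_data import ideal_helix_structure

for n in (46, 67, 96, 99, 125):
    print(f"n={n:4d} residues -> {count_double_insertions(n):>9,} double-insertion mutants")

# annotate the first few points of the space for a 46-residue scaffold
# with two helices (residues 7-17 and 23-30)
scaffold = ideal_helix_structure(46)
scaffold.helix_ranges = [(7, 17), (23, 30)]
scaffold.__post_init__()

print("\nfirst five mutants of the n=46 space:")
print("mutant_id  gaps      size_group  helix_group")
for di in islice(enumerate_double_insertions(46), 5):
    print(f"{di.mutant_id:<10} {di.gaps!s:<9} {pair_size_group(di):<11} "
          f"{helix_group_of(di, scaffold)}")

# a mutant with both insertions inside the first helix:
from insertscan import DoubleInsertion
di = DoubleInsertion(9, 12, "P", "W")   # gaps 8 and 10, both in helix 7-17
print(f"\n{di.mutant_id}: gaps {di.gaps}, group {helix_group_of(di, scaffold)}"
      " (both insertions interrupt a helix)")
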