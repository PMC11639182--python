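# Methods

This note records the models, conventions, defaults and known limitations
behind `insertscan`, in enough detail to reproduce or audit any number the
package emits.

## Mutant space

A double-insertion mutant of an *n*-residue protein is indexed by the
positions of the two inserted residues in the *elongated* (*n*+2)-long
sequence, 1-based with pos₁ < pos₂, plus the two inserted types. This
coordinate system counts C(*n*+2, 2) · 20² mutants — the convention under
which a 99-residue protein yields exactly 2,020,000 mutants — and it
represents two insertions at the same wildtype gap (adjacent elongated
positions) without double counting.

Positions map back to **wildtype insertion gaps** by gap₁ = pos₁ − 1 and
gap₂ = pos₂ − 2, where gap *g* ∈ 0..*n* is the slot between residue *g* and
residue *g*+1. The back-mapping makes each insertion's helix membership
independent of where the other insertion lands. A gap is *in a helix* only
when both flanking residues belong to the same annotated helix range —
the one placement that interrupts the helix — so terminal gaps never
qualify. All reported positions use wildtype gap numbering; the choice is
fixed here because mutant-frame numbering would shift with the other
insertion.

Helix groups: I_XX, I_XH, I_HH for zero, one or two insertions falling in
helices. Size classes partition the 20 amino acids by residue volume:
VS = {G,A,S} (60–89 Å³), S = {C,D,P,N,T} (108–116), M = {E,V,Q,H}
(138–153), L = {M,I,L,K,R} (162–173), VL = {F,Y,W} (189–227). A mutant
belongs to a single class when either inserted residue is in it and to a
homogeneous pair class (VSVS…VLVL) when both are; mixed pairs get labels
like `VS-VL`.

## Structure model and PDB handling

PDB reading and writing go through gemmi. Only the first model and first
chain are used (with a warning when more exist); HETATM records, waters and
residues without a bond template are dropped; residues are renumbered 1..*n*
in file order, keeping insertion-code residues in place. Helix annotations
come from HELIX records only — no secondary-structure recomputation — since
the deposited annotations are what define the helix groups. Structures
round-trip through the writer/reader to within the PDB fixed-decimal
precision (10⁻³ Å).

## Interactions

Covalent topology is inferred from per-residue heavy-atom bond templates
plus inter-residue peptide bonds; hydrogens are attached to the nearest
heavy atom in their residue. Bonds are *locked* (peptide C–N, carbonyl and
carboxylate/amidinium/amide double or partial-double bonds, aromatic and
proline rings, H attachments) or *rotatable* (everything else).

**Hydrogen bonds** use a geometric criterion: donor heavy atom D ∈ {N,O,S}
with implicit-H donor capability from residue templates (backbone amide N
of every non-proline residue, standard side-chain donors) or an explicit
attached H; acceptor A from lone-pair-bearing template atoms (carbonyl and
side-chain O, S, unprotonated ring N — the protonated backbone amide N is
never an acceptor); |D−A| ≤ 3.5 Å; if D has an explicit H, some H must give
∠(D–H···A) ≥ 120°, otherwise every covalent antecedent X of D must give
∠(X–D···A) ≥ 90°. Covalently bonded and 1-3 pairs are excluded and each
unordered pair is reported once. On an ideal 12-residue α-helix this finds
exactly the eight i → i−4 backbone bonds (the i → i−3 contact fails the
angle test at ≈109°, the intra-residue N···O pair at ≈28°). The criterion
is geometric rather than energy-based, so absolute counts are not
comparable with energy-scored tallies (an energy-based reference counts
9 bonds in wildtype crambin, for instance); all conclusions drawn from HBC
here are therefore comparative, and the cutoffs are configurable
(`InteractionConfig`).

**Hydrophobic tethers** join C/S atoms of different residues within the sum
of van der Waals radii (C 1.7 Å, S 1.8 Å) plus 0.25 Å slack. Pairs within
three covalent bonds (1-2, 1-3, 1-4) are excluded: a 1-4 distance is fixed
by a single torsion, and treating backbone C(i)–CB(i+1) contacts (2.7 Å in
any conformation) as stabilizing would rigidify even a fully extended
chain, contradicting the intended mechanics.

## Rigidity analysis

The body–bar–hinge graph takes atoms as bodies, merges bodies across locked
bonds, and connects bodies with bars: 5 for a rotatable bond (a hinge,
encoded by the standard 5-bar equivalence), 5 for a hydrogen bond, 2 for a
hydrophobic tether. Parallel constraints between one body pair are summed
and capped at 6 bars, since 6 generic bars already lock the pair.

The **(6,6) pebble game** runs over bars in lexicographic edge order: every
body holds 6 pebbles; a bar is independent iff 7 pebbles can be gathered on
its endpoints by depth-first searches over the directed graph of accepted
bars (with sorted adjacency, making the run bit-reproducible); accepting a
bar consumes one pebble. Independent + redundant bars always equals the
total. Rigid clusters are extracted pairwise: bodies u, v are mutually
rigid iff no rearrangement frees 7 pebbles on {u, v}; for 6-pebble body
frameworks mutual rigidity is transitive (two rigid clusters sharing a body
coincide), so a union-find grows the partition. The tests verify the
independent-bar count against a *generic rigidity-matrix rank* oracle
(random body placements and bar attachments, rank of the screw-coordinate
constraint matrix, max over 3 placements) on 200 random frameworks, the
cluster partition against a brute-force matrix null-space test, and
invariance of the decomposition to edge insertion order.

## Metrics

Cluster sizes are counted in atoms (the decomposition is atomic). With
sizes *s₁…s_c*, *N* = Σ*s_c*:

- CCE = −Σ (*s_c*/*N*) ln(*s_c*/*N*) / ln *N* (defined 0 at *N* = 1):
  the size-weighted Shannon entropy of the cluster distribution, 0 for one
  cluster, 1 for all singletons. The size-weighted form is chosen because
  it provably satisfies the stated range and the merge law (merging any
  two clusters strictly decreases it); a count-weighted variant would too,
  but the size-weighted form is the one whose weights are the probability
  that a random *atom* falls in a cluster, matching the flexibility
  interpretation. Exact numeric parity with other published CCE variants is
  not claimed.
- ROP = max(*s_c*)/*N*: the largest-cluster atom fraction. Merging clusters
  never decreases it; ROP = 1 ⇔ CCE = 0.

## Synthetic data

`ideal_helix_structure` builds poly-alanine with φ = −57°, ψ = −47°,
ω = 180° and standard internal coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å,
C–N 1.329 Å, C=O 1.231 Å, N–H 1.010 Å; angles C–N–Cα 121.7°, N–Cα–C 111.2°,
Cα–C–N 116.2°), with amide hydrogens placed trans to the preceding carbonyl
oxygen. `extended_chain_structure` uses φ = −120°, ψ = 120°. Atom placement
is by internal-coordinate chaining (NeRF), verified by round-tripping the
built torsions.

`simulate_metric_ensemble` draws each metric i.i.d. normal per mutant with
configurable base mean and sd, applies planted additive shifts (in sd
units) to annotation-defined subsets, and then rounds/floors hbc to a
non-negative integer and clips cce to [0,1] and rop to (0,1]. Defaults —
hbc (5.5, 1.5), cce (0.55, 0.08), rop (0.45, 0.08) — put the continuous
metrics ≥ 3 sd from their bounds so truncation bias is negligible and a
planted shift of δ sd is recovered as Cohen's d ≈ δ. Rounding hbc to
integers adds 1/12 to its variance, attenuating a planted d by the factor
σ/√(σ² + 1/12) ≈ 0.982 at σ = 1.5; recovery checks for exact δ therefore
use the continuous cce. Randomness comes from one numpy Generator consumed
in the deterministic enumeration order, so a seed fixes the table
byte-for-byte.

The generator emulates the *statistical* structure of a mutant ensemble —
annotated groups with controllable standardized mean separations and
normal-like noise — not the physics that produces it: no correlation
between metrics, no position-dependent effects beyond what is planted, no
heavy tails or multimodality from actual structural remodelling. Passing
recovery tests therefore demonstrates that the statistical layer measures
what it claims on data with known ground truth, not that real mutant
ensembles satisfy the normal model.

Default study conditions mirror a crambin-scale run: a 46-residue scaffold
with helices at residues 7–17 and 23–30 gives the full 451,200-row
ensemble used in the recovery tests (group sizes 186,000 / 204,000 /
61,200 for I_XX / I_XH / I_HH), with hbc's base mean 5.5 matching the
reported mutant-ensemble average at that scale.

## Statistics

Outlier sets are two-sided — |x − mean| ≥ kσ with k = 2 by default — with
mean and *population* sd over the whole ensemble (a one-sided variant is a
flag away). Under a normal null the expected 2σ outlier mass is 4.55%.
Effect sizes use *sample* (ddof = 1) sds and the root-mean-square pooled
form δ_pooled = √((δ₁² + δ₂²)/2); the accompanying test is the classical
pooled-variance Student t (Welch available via `equal_var=False`). No
multiple-testing correction is applied to the handful of group comparisons;
p-values are reported raw.

Size-group rates divide a group's outlier count by that group's ensemble
count (within-group fraction), which reduces to the ~4.55% null level for
every group under i.i.d. metrics; dividing by the whole-ensemble size
instead is available via `denominator="ensemble"`. Frequency tallies count
residue *occurrences* (a homotypic outlier pair contributes 2 to its
residue, 1 to its diagonal matrix cell); top-k rankings break count ties
lexicographically and report the five most frequent elements across the
selected pairs, weighted by pair count. The HBC-by-pair grid orders the 210
unordered residue pairs by summed volume from GG to WW (ties
lexicographic); a heterotypic cell averages the two insertion orders, and a
companion count grid supports exact conservation checks.

## Problem sizes and numerical choices

Test and validation workloads are sized for a laptop-class single CPU: the
pebble-game oracle sweep uses 200 frameworks of ≤ 8 bodies and ≤ 30 bars;
statistical recovery uses the full 451,200-row 46-residue ensemble (about
a second to generate); the t-test type-I simulation uses 10,000 replicates
of two n = 50 groups. Rank computations use numpy's SVD-based
`matrix_rank` with tolerance 10⁻⁸ on coordinates of order 10, far from the
rank decision boundary for generic placements. Degenerate inputs are
defined explicitly: CCE(N = 1) = 0; a zero-variance metric yields an empty
outlier set with a warning; helix-group comparisons skip pairs where a
group has n < 2.

## Known limitations

- The hydrogen-bond detector is geometric; absolute HBC values differ from
  energy-based counters, so only comparative statements are meaningful.
- Bar multiplicities (hinge 5, H-bond 5, hydrophobic 2) follow rigidity
  literature conventions but are conventions; they are configurable, and
  different choices shift CCE/ROP scales.
- Rigid-cluster extraction is O(bodies²) pebble queries — fine for small
  proteins and fixtures, not tuned for thousand-residue chains.
- The ensemble simulator models metric noise, not structure; conclusions
  about real mutant ensembles require real per-mutant metric tables, which
  the statistics layer accepts as plain CSV.
- mmCIF input is supported only as far as gemmi's reader maps it onto the
  same first-model/first-chain path; multi-chain analysis is out of scope.
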