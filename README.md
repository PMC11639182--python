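# insertscan

Analysis toolkit for **exhaustive double-insertion mutagenesis** of small
proteins: enumerate every mutant carrying two amino-acid insertions, score
each structure with rigidity-theoretic stability metrics, and locate the
insertion pairs, positions and residue classes with outsized structural
impact.

The package is aimed at structural bioinformaticians studying how insertion
mutations perturb protein stability, where the mutant space is too large for
experiment (an *n*-residue protein admits C(*n*+2, 2) · 20² double-insertion
mutants — 451,200 at *n* = 46, over 3 million at *n* = 125) and per-mutant
metrics must be cheap, mechanical and comparable.

## What it computes

**Mechanical model.** A protein is modelled as a *body–bar–hinge framework*:
atoms are rigid bodies; locked covalent bonds (peptide, double/partial
double, rings) merge atoms into larger bodies; rotatable bonds are hinges
(5 bars); geometrically detected hydrogen bonds contribute 5 bars and
hydrophobic tethers 2. The **(6,6) pebble game** decides which bars are
independent — a bar is accepted iff 7 free pebbles can be gathered on its
endpoint bodies — and partitions the structure into **rigid clusters**
(maximal body sets with zero internal relative motion). The implementation
is validated against an independent generic rigidity-matrix rank oracle.

**Per-mutant metrics.** From the atom-level cluster sizes *s₁…s_c* with
*N* = Σ*s_c*:

- **HBC** — hydrogen-bond count (geometric donor–acceptor criterion);
  more bonds ⇒ more stable.
- **CCE** — cluster configuration entropy
  *H* = −Σ (*s_c*/*N*) ln(*s_c*/*N*) / ln *N* ∈ [0, 1];
  0 = one rigid cluster, 1 = fully fragmented.
- **ROP** — rigidity order parameter max(*s_c*)/*N* ∈ (0, 1];
  the fraction of atoms in the dominant rigid cluster.

**Statistics.** Two-sided *k*σ outlier sets; residue, residue-pair and
position frequency tallies; top-*k* pair rankings; helix-group comparisons
(I_XX / I_XH / I_HH — neither / one / both insertions interrupting an
α-helix) scored with pooled-variance *t*-tests and Cohen's
*d* = (M₁ − M₂)/δ_pooled, δ_pooled = √((δ₁² + δ₂²)/2); and within-group
outlier rates by amino-acid volume class (VS/S/M/L/VL and the homogeneous
pairs VSVS…VLVL).

**Synthetic data.** Because building millions of mutant structures requires
a dedicated modelling pipeline, the package ships generators for every input
it needs: ideal-geometry α-helices and extended chains (with analytically
placed amide hydrogens), random bar frameworks, and simulated metric
ensembles over the full mutant space with *planted* standardized group
shifts for validating the statistical layer by parameter recovery.

## Worked example

```python
from insertscan import metric_record, helix_group_comparison
from insertscan.synthetic_data import (PlantedEffect, SyntheticEnsembleConfig,
                                       ideal_helix_structure,
                                       simulate_metric_ensemble)

# a 12-residue ideal helix: 8 backbone i -> i-4 hydrogen bonds
r = metric_record(ideal_helix_structure(12))
print(r.hbc, round(r.cce, 3), round(r.rop, 3))
# 8 0.291 0.75

# full 451,200-mutant ensemble for a 46-residue two-helix scaffold,
# with a planted helix effect on the hydrogen-bond count
scaffold = ideal_helix_structure(46)
scaffold.helix_ranges = [(7, 17), (23, 30)]
scaffold.__post_init__()
config = SyntheticEnsembleConfig(
    seed=17,
    planted_effects=[PlantedEffect(("helix_group", "I_HH"), "hbc", -0.456)])
ensemble = simulate_metric_ensemble(config, scaffold)
d = helix_group_comparison(ensemble, "hbc")["I_XX_vs_I_HH"]["effect"].d
print(round(d, 3))
# 0.449
```

The first line says the ideal helix is dominated by one rigid cluster
holding 75% of its atoms (ROP 0.75) with low cluster entropy (CCE 0.29).
The recovered Cohen's *d* ≈ 0.449 matches the planted −0.456 sd shift on the
helix-interrupting group (integer rounding of bond counts attenuates it by
about 2%).

Runnable, commented versions of this and the other capabilities live in
`examples/`. A thin CLI mirrors the library:

```bash
insertscan enumerate --n 46 --limit 10
insertscan simulate --n 46 --helix 7-17 --helix 23-30 \
    --plant I_HH:hbc:-0.456 --seed 17 --out ensemble.csv
insertscan run --n 46 --helix 7-17 --helix 23-30 --seed 17 --out run_out/
```

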