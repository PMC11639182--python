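"""Simulate a full mutant ensemble and recover a planted helix effect.

Builds the exhaustive 451,200-mutant ensemble for a 46-residue scaffold
with two helices, plants a depression of the hydrogen-bond count for
mutants whose insertions interrupt helices (moderate standardized shifts),
and recovers the effect with pooled-sd Cohen's d and a two-sample t-test.
"""

from insertscan import helix_group_comparison, outliers
from insertscan.synthetic_data import (PlantedEffect, SyntheticEnsembleConfig,
                                       ideal_helix_structure,
                                       simulate_metric_ensemble)

scaffold = ideal_helix_structure(46)
scaffold.helix_ranges = [(7, 17), (23, 30)]
scaffold.__post_init__()

config = SyntheticEnsembleConfig(
    seed=17,
    planted_effects=[
        PlantedEffect(("helix_group", "I_XH"), "hbc", -0.403),
        PlantedEffect(("helix_group", "I_HH"), "hbc", -0.456),
    ])
ensemble = simulate_metric_ensemble(config, scaffold)
group_sizes = {k: int(v) for k, v in
               ensemble.records["helix_group"].value_counts().items()}
print(f"simulated {len(ensemble):,} mutants ({group_sizes})")

print("\nhelix-group comparisons on hydrogen-bond count:")
for name, entry in helix_group_comparison(ensemble, "hbc").items():
    e = entry["effect"]
    print(f"  {name:<15} d={e.d:+.3f}  t={e.t:+9.2f}  p={e.p:.2e} "
          f"(n1={e.n1:,}, n2={e.n2:,})")

oset = outliers(ensemble, "rop", k=2.0)
print(f"\nnull ROP 2-sigma outliers: {len(oset):,} of {len(ensemble):,} "
      f"({100 * len(oset) / len(ensemble):.2f}%, expected ~4.55% for a "
      "normal metric)")
print("\nThe recovered d values match the planted shifts (the hbc rounding")
print("to integer counts attenuates them by ~2%).")
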