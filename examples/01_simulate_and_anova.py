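"""Simulate a balanced MET and partition its variance.

Generates a 34-genotype x 8-environment x 3-replicate trial with the
default variance structure (environment-dominated, low-rank
interaction), runs the joint ANOVA, and prints the ENV/GEN/GEI shares
of the three-way sum of squares.
"""

import metstab as ms

data, truth = ms.simulate_met(ms.SimConfig(seed=1))
print(f"dataset: {data.g} genotypes x {data.e} environments x {data.r} reps "
      f"= {len(data)} plots")

anova = ms.joint_anova(data)
print("\nJoint ANOVA (plot scale):")
print(anova.table.round(2).to_string())

pct_e, pct_g, pct_gei = ms.ss_proportions(anova)
print(f"\nThree-way SS shares: ENV {pct_e:.2f}%  GEN {pct_g:.2f}%  "
      f"GEI {pct_gei:.2f}%")
print("The environment dominates (as configured: 71.29/14.77/13.94); the",
      "GEI share is what the AMMI axes will decompose next.")
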