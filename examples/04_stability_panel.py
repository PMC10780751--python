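"""The full stability-index panel with ranks, and GY x WAAS quadrants.

Computes WAAS plus the parametric (Shukla, ecovalence, joint
regression, Annicchiarico, Lin & Binns, Tai, ...) and nonparametric
(Huehn, Thennarasu) indices, prints the consensus-stable genotypes and
the quadrant classification.
"""

import metstab as ms

data, _ = ms.simulate_met(ms.SimConfig(seed=1))
m = ms.cell_means(data)
anova = ms.joint_anova(data)
model = ms.fit_ammi(data, anova=anova)

tab = ms.stability_table(m, model=model, anova=anova)
cols = ["GY_R", "WAAS_R", "Shukla_R", "Ecoval_R", "Pi_a_R", "S1_R", "N1_R"]
summary = tab.ranks[cols].assign(mean_rank=tab.ranks[cols].mean(axis=1))
print("Most consensus-stable genotypes (mean of selected index ranks):")
print(summary.sort_values("mean_rank").head(6).round(1).to_string())

quads = ms.gy_waas_quadrants(m.gen_means, tab.values["WAAS"])
iv = list(quads.genotypes[quads.genotypes == "IV"].index)
print(f"\nQuadrant IV (high yield, low WAAS - broadly adapted): {iv}")
print("Quadrant I genotypes are low-yielding AND unstable; II are high")
print("yielding but environment-sensitive; III stable but low yielding.")
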