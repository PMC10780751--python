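"""GGE biplot geometry: which genotype won where, and who is 'ideal'.

Fits the environment-centered model, prints the winning genotype of
each environment's sector and the ideal-genotype ranking from the
average-environment-axis projection.
"""

import metstab as ms

data, _ = ms.simulate_met(ms.SimConfig(seed=1))
m = ms.cell_means(data)

www = ms.which_won_where(ms.fit_gge(m, svp="symmetric"))
print("Which-won-where (rank-2 model):")
print(f"  polygon vertices: {www.hull_vertices}")
for env in m.environments:
    sector = www.sector_of_env[env]
    print(f"  {env}: sector {sector}, winner {www.winner_of_sector[sector]}")

proj = ms.mean_vs_stability(ms.fit_gge(m, svp="genotype"))
top = proj.table.sort_values("rank").head(5)
print("\nMean-vs-stability ranking (distance to the ideal point):")
print(top.round(2).to_string())
print("Rank 1 combines high mean projection (yield) with small")
print("perpendicular distance from the average-environment axis (stability).")
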