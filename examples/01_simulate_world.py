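"""Generate a seeded synthetic world and inspect its structure.

The world bundles everything the coverage analysis consumes: a nested admin
partition, smooth covariate rasters, an under-5 population surface, ORS/RHF/
ORT coverage truths with rising-ORS / falling-RHF trends, cluster-level survey
records with small binomial denominators, and a mortality raster negatively
linked to ORS coverage.
"""

import numpy as np

import ortmap as om

world = om.simulate_world(om.WorldConfig(), seed=7)
grid = world.grid
obs = world.observations

print(f"grid: {grid.n_rows}x{grid.n_cols} cells, years {grid.years[0]}-{grid.years[-1]}")
print(f"admin units: {len(grid.units('country'))} countries, "
      f"{len(grid.units('admin1'))} admin1, {len(grid.units('admin2'))} admin2")
print(f"survey records: {len(obs)} "
      f"({(obs.geo_type == 'polygon').mean():.0%} polygon-referenced)")
print(f"median cluster denominator N: {obs['N'].median():.0f} children with diarrhoea")

for ind in ("ORS", "RHF", "ORT"):
    p = world.truths[ind].values[0]
    w = world.population.layer("population")
    first, last = [float((p[t] * w[t]).sum() / w[t].sum()) for t in (0, -1)]
    print(f"{ind}: population-weighted truth coverage {first:.3f} ({grid.years[0]}) "
          f"-> {last:.3f} ({grid.years[-1]})")

# mortality is negatively linked to ORS coverage by construction
p_last = world.truths["ORS"].values[0, -1]
d_last = world.mortality.layer("deaths")[-1] / world.population.layer("population")[-1]
print(f"cell-level corr(ORS coverage, death rate): "
      f"{np.corrcoef(p_last, d_last)[0, 1]:.3f}  (negative by design)")
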