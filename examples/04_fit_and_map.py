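"""Fit the space-time geostatistical model and map ORS coverage.

Stacked learners turn covariates into ensemble predictions; the Bayesian
binomial GP model (Matérn 3/2 in space x AR1 in time, Laplace-approximated
over a hyperparameter grid) smooths the survey data and yields 250 joint
posterior surface draws, which aggregate to admin2 units with population
weights and 95% uncertainty intervals.
"""

import numpy as np

import ortmap as om

cfg = om.WorldConfig(n_rows=16, n_cols=16, years=(2000, 2001, 2002, 2003),
                     n_countries=1, n_regions=1,
                     design=om.SurveyDesign(n_surveys=8, clusters_per_survey=40))
world = om.simulate_world(cfg, seed=11)
obs = world.observations
ors = obs[obs["indicator"] == "ORS"].reset_index(drop=True)

bundle = om.fit_child_learners(ors, world.covariates, seed=1)
design = om.stack_design(bundle)
print(f"child learners: {bundle.learners} (5-fold cross-fitted)")

fit = om.fit_mbg(ors, world.grid, pop=world.population, design=design)
post = fit.hyper_posterior().sort_values("weight", ascending=False)
top = post.iloc[0]
print(f"stacking weights: {dict(zip(fit.stack_names, np.round(fit.stack_weights, 3)))}")
print(f"top hyperparameter point: sigma2={top.sigma2_sp}, range={top.range_sp}, "
      f"rho_t={top.rho_t} (posterior weight {top.weight:.2f})")

cube = om.draw_posterior_surfaces(fit, n_draws=250, seed=2)
agg = om.aggregate_draws(cube, world.population, "admin2")
summary = agg.summary()
last = summary[summary["year"] == cfg.years[-1]]
print(f"\nadmin2 ORS coverage in {cfg.years[-1]} (mean [95% UI]):")
for row in last.head(4).itertuples():
    print(f"  unit {row.unit_id}: {row.mean:.3f} [{row.lower95:.3f}, {row.upper95:.3f}]")

# how well do the admin2 estimates recover the generative truth?
truth = world.truths["ORS"].values[0]
pop = world.population.layer("population")
truth_agg = [
    float((truth[-1, c] * pop[-1, c]).sum() / pop[-1, c].sum())
    for c in (world.grid.cells_of("admin2", u) for u in agg.units)
]
r = np.corrcoef(truth_agg, last["mean"])[0, 1]
print(f"\ncorrelation with truth aggregates: r = {r:.3f}")

aroc = om.compute_aroc(agg, cfg.years[0], cfg.years[-1]).summary()
n_sig = aroc["significant"].sum()
print(f"AROC (annualised logit change, %): mean {aroc['aroc_mean'].mean():+.1f}; "
      f"{n_sig}/{len(aroc)} units with a 95% UI excluding zero")
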