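"""Validate the model by admin2-blocked five-fold cross-validation.

Whole admin2 units are held out together so prediction is genuinely spatial.
Metrics: bias (mean error), RMSE, 95% data coverage within posterior-
predictive intervals, and correlation between observed and predicted
proportions.
"""

import ortmap as om

cfg = om.WorldConfig(n_rows=16, n_cols=16, years=(2000, 2001, 2002),
                     design=om.SurveyDesign(n_surveys=9, clusters_per_survey=40))
world = om.simulate_world(cfg, seed=23)
obs = world.observations
ors = obs[obs["indicator"] == "ORS"].reset_index(drop=True)

report = om.cross_validate(ors, world.grid, world.population, k=5, seed=0, n_draws=100)
p = report.pooled
print(f"pooled over {p['n']} held-out records:")
print(f"  bias       {p['bias']:+.4f}   (should be near 0)")
print(f"  rmse       {p['rmse']:.4f}   (binomial noise floor dominates at small N)")
print(f"  coverage95 {p['coverage95']:.3f}    (should sit near 0.95)")
print(f"  pearson r  {p['pearson_r']:.3f}")
print("\nper fold:")
print(report.per_fold[["fold", "n", "bias", "rmse", "coverage95", "pearson_r"]]
      .to_string(index=False))
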