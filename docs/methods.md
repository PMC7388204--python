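# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limitations of `ortmap`. It describes what the
code computes; every number quoted here is produced by the test suite or the
example scripts.

## 1. The estimation problem

The quantity of interest is treatment coverage: the proportion of children
under 5 with diarrhoea who received ORS, RHF, or either (ORT), per grid cell
and year, aggregated to administrative units. Observations are survey
clusters with a binomial numerator/denominator, georeferenced to a cell
("point" records) or to an admin1 polygon ("polygon" records). Denominators
are small — the denominator is children *with diarrhoea*, typically around
ten per cluster — so single clusters are extremely noisy and spatial
smoothing is essential.

## 2. Synthetic worlds

The generator (`ortmap.synthworld`) produces every input the analysis needs,
deterministically from a seed. It emulates the features of the real data
that matter for method correctness:

- **Geography.** An abstract unit-cell grid (default 30×30 cells, 6 years)
  with countries banded over rows (default 3), each split into 4 admin1
  quadrants of 4 admin2 quadrants (48 admin2 units), countries grouped into
  2 independent modelling regions. Cell centers give distances; there are no
  projections or real borders, which are irrelevant to the statistics.
- **Covariates.** 8 smooth standardized random fields (Gaussian-filtered
  noise), one of which is a near-linear combination of two others
  (R² > 0.9) so multicollinearity filtering has something to find. Layers
  are near-static in time with a small smooth drift.
- **Truth surfaces.** logit p = α + βᵀx + trend·(year − y₀) + GP, with the
  same separable Matérn(3/2) × AR1 field the model assumes (defaults
  σ² = 0.5, range 6 cells, ρ_t = 0.8). Defaults: ORS α = −0.8 with trend
  +0.08/yr, RHF α = −1.2 with trend −0.08/yr, emulating rising ORS and
  falling RHF. ORT = 1 − (1 − p_ORS)(1 − p_RHF), so ORT dominates both
  components cell-wise. Note that a single field realization can locally
  override the deterministic trend — the trend holds in expectation, not in
  every seed.
- **Surveys.** Surveys cycle over (country, year); cluster cells are drawn
  with probability proportional to population; N = 1 + Poisson(mean_N − 1)
  guarantees N ≥ 1 (default mean 10). A cluster-level nugget (sd 0.15 on the
  logit) adds overdispersion. A configurable fraction (default 10%) of
  records is polygon-referenced to an admin1 unit, observing the
  population-weighted mean coverage. For RHF, 30% of surveys report under a
  non-standard definition (logit offset −0.4), and a subset of those report
  both definitions, providing crosswalk calibration.
- **Mortality.** deaths = pop × base_rate × (1 − ε_link · p_ORS) with
  optional lognormal noise (defaults base rate 0.004, ε_link = 0.5), so the
  negative coverage–mortality link holds by construction. A diarrhoea
  episode layer (population × smooth prevalence ≈ 0.25) supports
  untreated-children counts; both are treated as fixed, uncertainty-free
  inputs downstream.

What the generator does *not* emulate: survey design effects and weighting,
recall bias, urban/rural stratification, real covariate semantics,
country-specific data gaps. Passing tests therefore demonstrate correctness
of the machinery under the assumed model class, not robustness to the many
ways real surveys violate it.

## 3. Definition crosswalk

Surveys reporting the same clusters under both the standard and a
non-standard RHF definition are pooled to survey-level proportions, and
logit(p_standard) = a + b·logit(p_nonstandard) is fitted by weighted least
squares on empirical logits (0.5 continuity correction at the boundaries),
weighted by the pooled denominators. Applying the model maps each
non-standard record's proportion through the fit and sets
k ← round(N·p̂) clamped to [0, N]. The crosswalk must be monotone; a fitted
slope ≤ 0 triggers a warning and an offset-only fallback (slope 1). The
calibration level (survey, not cluster or record) is a design choice; with
few calibration surveys the fit is weakly identified, and the generator's
`dual_definition_fraction` controls how much overlap exists.

## 4. Covariate filtering

Within each modelling region, VIF_j = 1/(1 − R²_j) is computed per layer on
pooled cell-year values; the highest-VIF layer is dropped (ties broken
lexicographically by name) and VIFs recomputed until all ≤ 3. Iterative
greedy removal rather than single-pass filtering is a deliberate choice:
it is standard practice and deterministic. Exact collinearity yields an
infinite sentinel; a single surviving column is assigned VIF 1.

## 5. Stacked generalisation

Three child learners of increasing flexibility are fitted to empirical-logit
working responses weighted by N: a ridge regression on covariates (penalty by
internal CV), a spline additive model on covariates plus space-time
coordinates (penalty by internal CV), and gradient-boosted depth-2 trees
(200 rounds, learning rate 0.05, minimum leaf size 20, early stopping on a
20% validation split). Each is cross-fitted over 5 cluster-level folds so a
record's out-of-fold (OOF) prediction never saw that record, and each
predicts the full raster; predictions are clipped to logit([1e-4, 1−1e-4]).
The early stopping and CV-chosen penalties keep all three learners near the
pooled mean when there is no covariate signal, a property the tests assert.

The ensembling weights are constrained to the simplex (non-negative, sum to
one) and fitted by maximising the binomial likelihood of the OOF predictions
(SLSQP). The combined stacker logit then enters the geostatistical model as
a unit-coefficient offset. Fitting the convex weights in a stacking step —
rather than jointly inside the Bayesian model — keeps the latent model
Gaussian and the Laplace approximation exact in form; it is the classical
stacked-generalisation recipe.

## 6. The geostatistical model and inference

Latent sites are the distinct observation cell-years (plus polygon member
cells, capped below). The prior over x = [α, u] is
α ~ N(0, 10²), u ~ N(0, Σ(θ)) with
Σ(θ) = σ² Matérn₃⁄₂(range) ⊗ AR1(ρ_t) + τ² I; the nugget τ² lives at the
cell-year site level (shared by co-located clusters), which keeps the latent
dimension at the number of distinct sites.

For each θ on a coarse grid (defaults: σ² ∈ {0.25, 0.5, 1, 2},
range ∈ {3, 6, 12}, ρ_t ∈ {0.3, 0.5, 0.7, 0.9}, τ² ∈ {0.01, 0.05}), the
posterior mode of x is found by damped Newton with line search, and the
marginal likelihood is Laplace-approximated:
log p(y|θ) ≈ ℓ(x̂) − ½x̂ᵀQx̂ + ½log|Q| − ½log|Q + W|, with weak hyperpriors
(log-normal on σ², range, τ²; Beta(2,2) on (ρ_t+1)/2). Grid points are mixed
by normalized weights. Against 2-D numerical quadrature on a single-site
problem the approximation agrees to better than 1e-3 relative error (tested).

Numerical choices:

- **Polygon likelihood** uses the population-weighted mean of cell-level
  probabilities (not a resampled point). Its exact gradient is used; the
  Hessian block uses the Gauss–Newton term only, which is negative
  semidefinite by construction and keeps Newton stable.
- **Polygon latent cap.** A polygon record contributes at most 12 member
  cells to the latent site set (largest populations first, weights
  renormalized). Without the cap, a handful of polygon records would drag
  every cell-year of their admin1 into the latent field and cube the fit
  cost; with it, the approximation error is the tail of the population
  weights, typically a few percent of the weighted mean.
- **Linear predictors** are clipped at ±35 before the inverse logit;
  correlation matrices carry a 1e-8 jitter.
- **Degenerate inputs**: empty observation sets, records outside the model
  region, polygons with zero population, and non-convergence of every grid
  point all raise errors (with diagnostics); individual non-converged grid
  points are dropped from the mixture with a warning.

**Joint draws.** Each of the (default 250) draws samples a grid point θ by
posterior weight, the latent sites from that component's Gaussian
approximation, and then a conditional simulation of the field on the full
grid: an unconditional draw via the Kronecker factorisation
(L_t Z L_sᵀ) is corrected by kriging against the site residuals. Draws are
joint surfaces — every downstream quantity (aggregates, AROC, counts,
counterfactuals) is computed per draw and summarised afterwards, so
uncertainty propagates coherently. The surface draws exclude the nugget
(it is observation noise); posterior-predictive checks for held-out records
add it back.

Regions are fitted independently; per-region draw cubes are stitched into
one grid. A simulation-based check (25 replicates at 30×30 cells × 4 years,
600 clusters) verifies that the 95% credible intervals for α and ρ_t cover
the generative truth in at least 80% of replicates; ρ_t's posterior is
discrete on the grid, so its intervals are conservative between grid points.

## 7. Aggregation and summaries

Unit aggregates are population-weighted means of cell draws; uncertainty
intervals are the 2.5th/97.5th draw percentiles under the
linear-interpolation percentile rule (the only rule used anywhere in the
package). AROC is computed per draw as the annualised logit difference,
reported in percent, with significance defined as the 95% UI excluding zero;
the logit (rather than log-ratio) scale is a documented choice, switchable in
principle but fixed by default. Untreated-children counts multiply the fixed
episode raster by (1 − p) per draw. Reported shares follow the package's
reporting rule: percentages rounded to one decimal for unit counts and to
integers for country counts.

## 8. Inequality metrics

The Gini coefficient over a country's admin2 units is population-weighted,
G = Σᵢⱼ wᵢwⱼ|xᵢ − xⱼ| / (2 x̄_w), computed in O(n log n) via the sorted
cumulative form and validated against the brute-force pairwise sum. Computing
it over admin2 units weighted by population (rather than unweighted) reflects
the reading that inequality is over the *population's* distribution of
coverage. Metrics default to draw means; per-draw computation is a
straightforward extension. Absolute deviation is reported in percentage
points, relative deviation in percent of the country mean (undefined and
NaN-flagged at a zero mean).

## 9. Counterfactual mortality

The effectiveness model is linear: a fraction ε·c of diarrhoeal deaths is
prevented at coverage c. The main scenario calibrates ε = 0.92 from the
anchor "69% of deaths averted at 75% coverage". (An alternative published
anchor, 93% at full coverage, is inconsistent with this at rounding level;
the 0.69@0.75 anchor is the one the counterfactual itself uses, so it wins.)
The halved scenario is anchored at a 35% reduction at 75% coverage
(ε = 0.4667) — the published sensitivity anchor, not ε/2 — and the doubled
scenario uses 2ε capped below 1/max(c) with a warning. Given observed deaths
D and coverage c, baseline no-ORS deaths are D/(1 − εc), so

- attributable = D·ε(1 − c)/(1 − εc),
- averted by c₀ → c₁ (evaluated at the later year's deaths) =
  D·ε(c₁ − c₀)/(1 − εc₁), signed: negative values are deaths due to
  coverage declines.

Both are computed per unit per posterior draw; demographic change and other
risk factors are deliberately ignored (coverage is treated as an independent
risk factor).

## 10. Cross-validation

Folds block at the admin2 level: all records of a unit share a fold, units
are assigned to 5 folds greedily by record count after a seeded shuffle, and
polygon records (which span multiple admin2 units) follow the smallest
admin2 id in their polygon. Metrics on held-out records: bias (mean error of
observed proportion minus posterior mean), RMSE, Pearson correlation, and
95% data coverage under the *posterior-predictive* distribution — k draws
are simulated as Binomial(N, p_draw) including the nugget, and coverage
counts records inside the 2.5–97.5 percentile of those draws. The
posterior-predictive (rather than latent-p) target is the right calibration
check for binomial counts; its discreteness makes nominal 95% coverage land
slightly above 0.95 at small N, hence the accepted band [0.88, 0.99].

## 11. Pipeline and problem sizes

`run_pipeline` chains simulate → crosswalk → vif → stack → fit → predict →
aggregate → inequality → counterfactual → validate, with all randomness
derived from one seed and a manifest recording stage order, output hashes,
and seeds; reruns are bit-identical. The pipeline's default hyperparameter
grid is a 27-point subset of the model default (σ² ∈ {0.25, 1, 2},
range ∈ {3, 6, 12}, ρ_t ∈ {0.4, 0.7, 0.9}, τ² = 0.02): the pipeline fits six
indicator-region models plus five CV refits, and the lean grid keeps the
whole chain at desk scale (minutes on one CPU) while leaving the recovery
diagnostics (admin2 truth correlation ≈ 0.83–0.93 across indicators at the
default seed) comfortably strong. Simulation-scale defaults throughout
(grid size, cluster counts, 250 draws) were chosen once as a realistic
desk-scale analogue of a multi-country study and are not tuned per run.

## 12. Known limitations

- Inference is empirical-Bayes over a discrete hyperparameter grid: between
  grid points, hyperparameter uncertainty is understated and ρ_t's posterior
  is a point mass mixture. An MCMC backend would remove this at substantial
  cost; the grid is the documented default and the only backend provided.
- The Laplace approximation is exact only as the Gaussian limit; at very
  small counts per site it slightly overstates precision (the CV calibration
  band absorbs this).
- The polygon cap (12 cells) is an approximation for very large polygons.
- The crosswalk models a single binary definition axis; the real diversity
  of RHF formulations collapses onto one offset.
- Counterfactual results inherit every simplification of the linear
  effectiveness model; they are accounting identities, not causal estimates.
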