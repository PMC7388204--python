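import numpy as np
import pytest
from scipy.special import logit
from scipy.stats import norm

import ortmap as om
from ortmap.synthworld import validate_observations


class TestCovariates:
    def test_seeded_determinism(self, small_grid):
        a = om.simulate_covariates(small_grid, 8, 1, seed=7)
        b = om.simulate_covariates(small_grid, 8, 1, seed=7)
        assert np.array_equal(a.values, b.values)
        c = om.simulate_covariates(small_grid, 8, 1, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_layers_standardized(self, small_grid):
        covs = om.simulate_covariates(small_grid, 6, 1, seed=3)
        flat = covs.values[:, 0, :]
        assert np.allclose(flat.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(flat.std(axis=1), 1.0, atol=1e-6)

    def test_collinear_layer_has_high_r2(self, small_grid):
        covs = om.simulate_covariates(small_grid, 8, 1, seed=11)
        X = covs.values[:, 0, :].T  # cells x layers
        # squared multiple correlation of each layer on the others, by least squares
        r2 = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ coef
            r2.append(1 - resid @ resid / (X[:, j] @ X[:, j]))
        assert max(r2) > 0.9

    def test_preconditions(self, small_grid):
        with pytest.raises(ValueError):
            om.simulate_covariates(small_grid, 1, 1, seed=0)
        with pytest.raises(ValueError):
            om.simulate_covariates(small_grid, 3, 3, seed=0)


class TestTruth:
    def test_identity_case_is_half(self, small_grid):
        covs = om.simulate_covariates(small_grid, 4, 0, seed=0)
        tp = om.TruthParams(alpha=0.0, beta=np.zeros(4), sigma2_sp=0.0, trend=0.0)
        truth = om.simulate_truth(small_grid, covs, tp, seed=1)
        assert np.allclose(truth.values, 0.5)

    def test_trend_monotone_in_year(self, small_grid):
        covs = om.simulate_covariates(small_grid, 4, 0, seed=0)
        tp = om.TruthParams(alpha=-0.3, beta=np.zeros(4), sigma2_sp=0.0, trend=0.2)
        p = om.simulate_truth(small_grid, covs, tp, seed=1).values[0]
        assert np.all(np.diff(p, axis=0) > 0)

    def test_beta_length_mismatch(self, small_grid):
        covs = om.simulate_covariates(small_grid, 4, 0, seed=0)
        with pytest.raises(ValueError, match="beta"):
            om.simulate_truth(small_grid, covs, om.TruthParams(beta=np.zeros(3)), seed=1)

    def test_variogram_increases_with_distance(self):
        """Monte-Carlo variogram of logit p rises with lag below the range."""
        grid = om.default_grid(14, 14, years=(2000,))
        covs = om.simulate_covariates(grid, 2, 0, seed=0)
        tp = om.TruthParams(alpha=0, beta=np.zeros(2), sigma2_sp=1.0, range_sp=5.0, rho_t=0.5)
        coords = grid.cell_coords()
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(coords))
        lags = [1.0, 2.0, 4.0]
        gamma = np.zeros(len(lags))
        for rep in range(100):
            eta = logit(om.simulate_truth(grid, covs, tp, seed=rep).values[0, 0])
            for li, lag in enumerate(lags):
                mask = np.abs(D - lag) < 0.26
                iu = np.triu_indices_from(D, 1)
                sel = mask[iu]
                diffs = eta[iu[0][sel]] - eta[iu[1][sel]]
                gamma[li] += 0.5 * np.mean(diffs**2)
        gamma /= 100
        assert gamma[0] < gamma[1] < gamma[2]

    def test_ort_dominates_components(self, small_world):
        for ind in ("ORS", "RHF"):
            assert np.all(
                small_world.truths["ORT"].values >= small_world.truths[ind].values - 1e-12
            )


class TestSurveys:
    def test_full_coverage_boundary(self, small_grid):
        covs = om.simulate_covariates(small_grid, 2, 0, seed=0)
        truth = om.RasterCube(
            np.ones((1, small_grid.n_years, small_grid.n_cells)), ["p_ORS"], small_grid
        )
        pop = om.simulate_population(small_grid, seed=1)
        obs = om.simulate_surveys(truth, pop, om.SurveyDesign(n_surveys=6, nugget_sd=0.0), seed=2)
        assert (obs["k"] == obs["N"]).all()

    def test_zero_offset_definitions_exchangeable(self, small_grid):
        """With no definition offset, standard vs nonstandard proportions agree
        (two-sample z-test on pooled records, alpha = 0.01)."""
        covs = om.simulate_covariates(small_grid, 2, 0, seed=0)
        tp = om.TruthParams(alpha=-0.4, beta=np.zeros(2), sigma2_sp=0.3)
        truth = om.simulate_truth(small_grid, covs, tp, seed=5)
        pop = om.simulate_population(small_grid, seed=1)
        des = om.SurveyDesign(
            n_surveys=12, clusters_per_survey=100, defn_offset=0.0,
            nonstandard_fraction=0.5, dual_definition_fraction=1.0,
        )
        obs = om.simulate_surveys(truth, pop, des, seed=3, indicator="RHF")
        a = obs[obs["definition"] == "standard"]
        b = obs[obs["definition"] == "nonstandard"]
        p1, n1 = a["k"].sum() / a["N"].sum(), a["N"].sum()
        p2, n2 = b["k"].sum() / b["N"].sum(), b["N"].sum()
        pool = (a["k"].sum() + b["k"].sum()) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert abs(z) < norm.ppf(0.995)

    def test_pooled_estimate_matches_weighted_mean(self, small_grid):
        """Pooled k/N estimates the population-weighted mean coverage within
        3 binomial Monte-Carlo standard errors."""
        covs = om.simulate_covariates(small_grid, 2, 0, seed=0)
        tp = om.TruthParams(alpha=-0.4, beta=np.zeros(2), sigma2_sp=0.2, trend=0.0)
        truth = om.simulate_truth(small_grid, covs, tp, seed=5)
        pop = om.simulate_population(small_grid, seed=1)
        des = om.SurveyDesign(
            n_surveys=small_grid.n_years * 3, clusters_per_survey=200, mean_N=10,
            polygon_fraction=0.0, nugget_sd=0.0,
        )
        obs = om.simulate_surveys(truth, pop, des, seed=9)
        p_w = float(
            (truth.values[0] * pop.layer("population")).sum() / pop.layer("population").sum()
        )
        n_tot = obs["N"].sum()
        p_hat = obs["k"].sum() / n_tot
        se = np.sqrt(p_w * (1 - p_w) / n_tot)
        # cluster sampling is with unequal p; allow design effect headroom inside 3 SE x 2
        assert abs(p_hat - p_w) < 3 * se * 2

    def test_record_invariants_bulk(self, small_world):
        validate_observations(small_world.observations)
        obs = small_world.observations
        assert (obs.loc[obs["geo_type"] == "point", "cell_id"] >= 0).all()
        assert (obs.loc[obs["geo_type"] == "polygon", "polygon_id"] >= 0).all()

    def test_zero_population_errors(self, small_grid):
        truth = om.RasterCube(
            np.full((1, small_grid.n_years, small_grid.n_cells), 0.5), ["p_ORS"], small_grid
        )
        pop = om.RasterCube(
            np.zeros((2, small_grid.n_years, small_grid.n_cells)),
            ["population", "episodes"],
            small_grid,
        )
        with pytest.raises(ValueError, match="population"):
            om.simulate_surveys(truth, pop, om.SurveyDesign(), seed=0)


class TestMortality:
    def _flat_truth(self, grid, p):
        return om.RasterCube(np.full((1, grid.n_years, grid.n_cells), p), ["p_ORS"], grid)

    def test_closed_form_reduction(self, small_grid):
        pop = om.simulate_population(small_grid, seed=0)
        truth = self._flat_truth(small_grid, 0.75)
        mort = om.simulate_mortality(truth, pop, om.MortalityLink(base_rate=0.01, epsilon=0.92))
        rate = mort.layer("deaths") / pop.layer("population")
        assert np.allclose(rate, 0.01 * (1 - 0.92 * 0.75))  # = base_rate * 0.31

    def test_epsilon_zero_rate_independent_of_coverage(self, small_grid):
        covs = om.simulate_covariates(small_grid, 2, 0, seed=0)
        truth = om.simulate_truth(small_grid, covs, om.TruthParams(beta=np.zeros(2)), seed=1)
        pop = om.simulate_population(small_grid, seed=0)
        mort = om.simulate_mortality(truth, pop, om.MortalityLink(epsilon=0.0))
        # with no link the death rate is flat regardless of coverage variation
        rate = mort.layer("deaths") / pop.layer("population")
        assert np.allclose(rate, om.MortalityLink().base_rate)
        assert truth.values[0].std() > 0

    def test_noiseless_perfect_anticorrelation_over_years(self, small_grid):
        covs = om.simulate_covariates(small_grid, 2, 0, seed=0)
        tp = om.TruthParams(alpha=0.0, beta=np.zeros(2), sigma2_sp=0.5, rho_t=0.5, trend=0.1)
        truth = om.simulate_truth(small_grid, covs, tp, seed=2)
        pop = om.simulate_population(small_grid, seed=0)
        mort = om.simulate_mortality(truth, pop, om.MortalityLink(epsilon=0.5, noise_sd=0.0))
        p = truth.values[0]
        d = mort.layer("deaths")
        for c in range(0, small_grid.n_cells, 17):
            if p[:, c].std() > 1e-9:
                assert np.corrcoef(p[:, c], d[:, c])[0, 1] == pytest.approx(-1.0)

    def test_epsilon_bound(self, small_grid):
        with pytest.raises(ValueError):
            om.MortalityLink(epsilon=1.0)


def test_world_determinism():
    cfg = om.WorldConfig(n_rows=8, n_cols=8, years=(2000, 2001),
                         design=om.SurveyDesign(n_surveys=4, clusters_per_survey=10))
    w1 = om.simulate_world(cfg, seed=3)
    w2 = om.simulate_world(cfg, seed=3)
    assert np.array_equal(w1.covariates.values, w2.covariates.values)
    assert w1.observations.equals(w2.observations)
    assert np.array_equal(w1.mortality.values, w2.mortality.values)
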