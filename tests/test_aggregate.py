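import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import ortmap as om
from ortmap.aggregate import share_percent
from ortmap.mbg import PosteriorDrawCube


def _uniform_cube(grid, value, n_draws=8):
    p = np.full((n_draws, grid.n_years, grid.n_cells), value)
    return PosteriorDrawCube(p, np.arange(grid.n_cells), grid)


def _random_cube(grid, seed, n_draws=16):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=(n_draws, grid.n_years, grid.n_cells))
    return PosteriorDrawCube(p, np.arange(grid.n_cells), grid)


class TestAggregateDraws:
    def test_constant_field_is_exact(self, small_grid):
        pop = om.simulate_population(small_grid, seed=0)
        agg = om.aggregate_draws(_uniform_cube(small_grid, 0.42), pop, "admin2")
        assert np.allclose(agg.draws, 0.42)

    def test_two_cell_weighted_mean(self):
        grid = om.default_grid(2, 2, years=(2000,), n_countries=1, n_regions=1)
        p = np.zeros((1, 1, 4))
        p[0, 0] = [0.2, 0.4, 0.2, 0.4]
        pop_vals = np.array([[[100.0, 300.0, 100.0, 300.0]]])
        pop = om.RasterCube(
            np.concatenate([pop_vals, pop_vals]), ["population", "episodes"], grid
        )
        cube = PosteriorDrawCube(np.repeat(p, 2, axis=0), np.arange(4), grid)
        agg = om.aggregate_draws(cube, pop, "country")
        assert np.allclose(agg.draws, 0.35)  # (100*0.2 + 300*0.4) / 400

    def test_country_equals_weighted_admin1(self, small_grid):
        pop = om.simulate_population(small_grid, seed=1)
        cube = _random_cube(small_grid, seed=2)
        country = om.aggregate_draws(cube, pop, "country")
        admin1 = om.aggregate_draws(cube, pop, "admin1")
        a1_country = {
            int(u): int(small_grid.country_of_cell[small_grid.cells_of("admin1", u)[0]])
            for u in small_grid.units("admin1")
        }
        for ci, c in enumerate(country.units):
            idx = [i for i, u in enumerate(admin1.units) if a1_country[int(u)] == c]
            w = admin1.population[idx]  # (n_units, n_years)
            expected = (
                np.einsum("uyd,uy->yd", admin1.draws[idx], w) / w.sum(axis=0)[:, None]
            )
            assert np.allclose(country.draws[ci], expected)

    def test_matches_bruteforce_on_random_instance(self, small_grid):
        pop = om.simulate_population(small_grid, seed=3)
        cube = _random_cube(small_grid, seed=4, n_draws=5)
        agg = om.aggregate_draws(cube, pop, "admin2")
        u = agg.units[7]
        cells = small_grid.cells_of("admin2", u)
        w = pop.layer("population")[1, cells]
        expected = np.sum(w * cube.p_draws[3, 1, cells]) / w.sum()
        i = list(agg.units).index(u)
        assert agg.draws[i, 1, 3] == pytest.approx(expected, rel=1e-12)


class TestSummarizeUi:
    def test_degenerate_draws(self):
        assert om.summarize_ui(np.full(250, 0.3)) == (0.3, 0.3, 0.3)

    def test_percentile_rule_oracle(self):
        draws = np.arange(1, 101) / 100.0
        mean, lo, hi = om.summarize_ui(draws)
        # linear interpolation between order statistics: index 99 * 0.025 =
        # 2.475 -> 0.03475; by symmetry the upper bound is 1.01 - 0.03475
        assert lo == pytest.approx(0.03475)
        assert hi == pytest.approx(0.97525)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        draws = rng.uniform(size=250)
        assert om.summarize_ui(draws) == om.summarize_ui(rng.permutation(draws))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            om.summarize_ui(np.array([0.1, np.nan]))

    def test_interval_nesting(self):
        rng = np.random.default_rng(1)
        draws = rng.uniform(size=250)
        _, lo95, hi95 = om.summarize_ui(draws)
        lo80, hi80 = np.percentile(draws, [10, 90])
        assert lo95 <= lo80 <= hi80 <= hi95


class TestAroc:
    def _agg(self, p0, p1, units=3):
        draws = np.zeros((units, 2, len(p0)))
        draws[:, 0, :] = p0
        draws[:, 1, :] = p1
        return om.AdminAggregate(draws, np.arange(units), (2000, 2017), "admin2",
                                 np.ones((units, 2)))

    def test_no_change_not_significant(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.2, 0.8, 50)
        rec = om.compute_aroc(self._agg(p, p), 2000, 2017)
        s = rec.summary()
        assert np.allclose(s["aroc_mean"], 0.0)
        assert not s["significant"].any()

    def test_logit_arithmetic_oracle(self):
        rec = om.compute_aroc(self._agg([0.12, 0.12], [0.339, 0.339]), 2000, 2017)
        expected = 100 * (logit(0.339) - logit(0.12)) / 17  # = 7.79%
        assert rec.summary()["aroc_mean"].iloc[0] == pytest.approx(expected)
        assert expected == pytest.approx(7.79, abs=0.005)

    def test_all_positive_draws_significant(self):
        rng = np.random.default_rng(3)
        p0 = rng.uniform(0.2, 0.3, 40)
        rec = om.compute_aroc(self._agg(p0, p0 + 0.3), 2000, 2017)
        assert rec.summary()["significant"].all()

    def test_boundary_probabilities_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            rec = om.compute_aroc(self._agg([0.0, 0.5], [0.5, 1.0]), 2000, 2017)
        assert np.all(np.isfinite(rec.draws))


class TestUntreated:
    def test_full_coverage_zero_untreated(self, small_grid):
        pop = om.simulate_population(small_grid, seed=0)
        out = om.count_untreated(_uniform_cube(small_grid, 1.0), pop)
        assert np.allclose(out["mean"], 0.0)

    def test_single_cell_arithmetic(self):
        grid = om.default_grid(2, 2, years=(2000,), n_countries=1, n_regions=1)
        epi = np.zeros((1, 1, 4))
        epi[0, 0, 0] = 100.0
        pop = om.RasterCube(np.concatenate([epi, epi]), ["population", "episodes"], grid)
        out = om.count_untreated(_uniform_cube(grid, 0.4, n_draws=4), pop)
        total = out[out["unit_id"] == -1]
        assert np.allclose(total["mean"], 60.0)  # 100 episodes * (1 - 0.4)

    def test_unit_counts_sum_to_total(self, small_grid):
        pop = om.simulate_population(small_grid, seed=1)
        cube = _random_cube(small_grid, seed=5)
        out = om.count_untreated(cube, pop)
        for year in small_grid.years:
            sub = out[out["year"] == year]
            assert sub[sub["unit_id"] >= 0]["mean"].sum() == pytest.approx(
                sub[sub["unit_id"] == -1]["mean"].iloc[0]
            )

    def test_monotone_in_coverage(self, small_grid):
        pop = om.simulate_population(small_grid, seed=1)
        lo = om.count_untreated(_uniform_cube(small_grid, 0.3), pop)
        hi = om.count_untreated(_uniform_cube(small_grid, 0.6), pop)
        assert (hi["mean"].to_numpy() <= lo["mean"].to_numpy() + 1e-9).all()


class TestProportionBelow:
    def _agg_with_means(self, means):
        draws = np.tile(np.asarray(means)[:, None, None], (1, 1, 4))
        return om.AdminAggregate(draws, np.arange(len(means)), (2017,), "admin2",
                                 np.ones((len(means), 1)))

    def test_share_percent_reporting_rule(self):
        assert share_percent(12417, 19823, 1) == 62.6
        assert share_percent(63, 94, 0) == 67.0

    def test_all_above_threshold(self):
        out = om.proportion_below(self._agg_with_means([0.6, 0.7, 0.9]), 0.5, 2017)
        assert out == {"count": 0, "total": 3, "percent": 0.0}

    def test_threshold_one_catches_all(self):
        out = om.proportion_below(self._agg_with_means([0.6, 0.7, 0.9]), 1.0, 2017)
        assert out["count"] == 3 and out["percent"] == 100.0


class TestCorrelateTrends:
    def _series(self, mat, units=None):
        mat = np.asarray(mat, float)
        units = units if units is not None else np.arange(mat.shape[0])
        return pd.DataFrame(mat, index=units, columns=[2000, 2001, 2002, 2003][: mat.shape[1]])

    def test_exact_anticorrelation(self):
        a = self._series([[0.1, 0.2, 0.3]])
        b = self._series([[0.9, 0.6, 0.3]])
        out = om.correlate_trends(a, b)
        assert out["per_unit"].iloc[0] == pytest.approx(-1.0)
        assert out["n_negative"] == 1

    def test_identical_series(self):
        a = self._series([[0.1, 0.2, 0.3]])
        out = om.correlate_trends(a, a)
        assert out["per_unit"].iloc[0] == pytest.approx(1.0)

    def test_matches_bruteforce_pearson(self):
        a = self._series([[0.12, 0.25, 0.21, 0.4]])
        b = self._series([[0.5, 0.45, 0.52, 0.3]])
        x, y = a.iloc[0].to_numpy(), b.iloc[0].to_numpy()
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert om.correlate_trends(a, b)["per_unit"].iloc[0] == pytest.approx(r)

    def test_zero_variance_excluded_from_denominator(self):
        a = self._series([[0.1, 0.2, 0.3], [0.5, 0.5, 0.5]])
        b = self._series([[0.3, 0.2, 0.1], [0.2, 0.3, 0.4]])
        out = om.correlate_trends(a, b)
        assert out["n_valid"] == 1 and out["n_zero_variance"] == 1
        assert out["percent_negative"] == 100.0
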