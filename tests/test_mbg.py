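import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import binom

import ortmap as om
from ortmap.mbg import HyperGrid, ModelSpec, _laplace_one, _prepare_obs
from ortmap.synthworld import OBS_COLUMNS


def _point_obs(rows):
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


class TestLogLikelihood:
    def test_single_record_closed_form(self, small_grid):
        p = np.full((small_grid.n_years, small_grid.n_cells), 0.5)
        obs = _point_obs([(0, 2000, "point", 0, -1, 2, 1, "ORS", "standard")])
        # Binomial(2, 0.5) at k=1 has probability 0.5
        ll = om.log_likelihood(p, obs, small_grid)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_matches_bruteforce_sum(self, small_grid):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, size=(small_grid.n_years, small_grid.n_cells))
        rows = []
        for i in range(50):
            N = int(rng.integers(1, 30))
            rows.append(
                (i, int(rng.choice(small_grid.years)), "point",
                 int(rng.integers(small_grid.n_cells)), -1, N, int(rng.integers(0, N + 1)),
                 "ORS", "standard")
            )
        obs = _point_obs(rows)
        expected = sum(
            binom.logpmf(r.k, r.N, p[small_grid.years.index(r.year), r.cell_id])
            for r in obs.itertuples()
        )
        assert om.log_likelihood(p, obs, small_grid) == pytest.approx(expected, rel=1e-10)

    def test_polygon_uses_weighted_mean_probability(self):
        grid = om.default_grid(4, 4, years=(2000,), n_countries=1, n_regions=1)
        # admin1 unit 0: set two of its cells to 0.2/0.4 with equal population
        a1_cells = grid.cells_of("admin1", 0)
        p = np.full((1, grid.n_cells), 0.3)
        p[0, a1_cells] = 0.3
        p[0, a1_cells[0]] = 0.2
        p[0, a1_cells[1]] = 0.4
        keep = a1_cells[:2]
        pop_vals = np.zeros((2, 1, grid.n_cells))
        pop_vals[0, 0, keep] = 50.0  # equal weights on the two cells
        pop = om.RasterCube(np.concatenate([pop_vals[0:1], pop_vals[0:1]]), ["population", "episodes"], grid)
        obs = _point_obs([(0, 2000, "polygon", -1, 0, 10, 3, "ORS", "standard")])
        ll = om.log_likelihood(p, obs, grid, pop)
        assert ll == pytest.approx(binom.logpmf(3, 10, 0.3), rel=1e-10)

    def test_missing_cell_errors(self, small_grid):
        p = np.full((small_grid.n_years, small_grid.n_cells), 0.5)
        obs = _point_obs([(0, 2000, "point", 10**6, -1, 2, 1, "ORS", "standard")])
        with pytest.raises(ValueError, match="cell"):
            om.log_likelihood(p, obs, small_grid)


class TestLaplaceAccuracy:
    def test_marginal_likelihood_matches_quadrature(self):
        """2-D numerical integration over (alpha, u) at a single latent site
        reproduces the Laplace log marginal within 1e-3 relative error."""
        from scipy.integrate import dblquad

        grid = om.default_grid(2, 2, years=(2000,), n_countries=1, n_regions=1)
        obs = _point_obs([(0, 2000, "point", 0, -1, 120, 50, "ORS", "standard")])
        spec = om.ModelSpec(alpha_prior_sd=1.5)
        cells = np.arange(grid.n_cells)
        cell_pos = {c: c for c in cells}
        data = _prepare_obs(obs, grid, None, cells, cell_pos, None)
        theta = (0.8, 2.0, 0.5, 0.05)
        mode, logml, _, conv, _ = _laplace_one(
            theta, data, grid.cell_coords(), 1, spec, np.zeros(2)
        )
        assert conv
        from ortmap.mbg import _log_hyperprior

        s2 = 0.8 + 0.05 + 1e-8  # site marginal variance incl. nugget + jitter
        const = data.logpmf_const

        def integrand(u, a):
            p = expit(a + u)
            return (
                np.exp(const + 50 * np.log(p) + 70 * np.log1p(-p))
                * np.exp(-0.5 * a**2 / 1.5**2) / np.sqrt(2 * np.pi * 1.5**2)
                * np.exp(-0.5 * u**2 / s2) / np.sqrt(2 * np.pi * s2)
            )

        val, _ = dblquad(integrand, -6, 6, lambda a: -6, lambda a: 6, epsabs=1e-12)
        expected = np.log(val) + _log_hyperprior(theta)
        assert logml == pytest.approx(expected, rel=1e-3)


class TestFit:
    def test_intercept_recovery_flat_world(self):
        """2000 Bernoulli observations at p = 0.3 with no spatial signal:
        posterior mean intercept within 0.15 of logit(0.3)."""
        grid = om.default_grid(10, 10, years=(2000,), n_countries=1, n_regions=1)
        rng = np.random.default_rng(8)
        rows = [
            (0, 2000, "point", int(rng.integers(100)), -1, 1, int(rng.random() < 0.3),
             "ORS", "standard")
            for _ in range(2000)
        ]
        fit = om.fit_mbg(
            _point_obs(rows), grid,
            spec=ModelSpec(hyper=HyperGrid(sigma2_sp=(0.05, 0.25), range_sp=(3.0,),
                                           rho_t=(0.5,), tau2=(0.01,))),
        )
        post_alpha = sum(c.weight * c.mode[0] for c in fit.components)
        assert post_alpha == pytest.approx(logit(0.3), abs=0.15)

    def test_empty_obs_errors(self, small_grid):
        with pytest.raises(ValueError, match="empty"):
            om.fit_mbg(_point_obs([]), small_grid)

    def test_out_of_region_record_errors(self, small_world):
        grid = small_world.grid
        region1_cell = int(np.flatnonzero(grid.region_of_cell == 1)[0])
        obs = _point_obs([(0, 2000, "point", region1_cell, -1, 5, 2, "ORS", "standard")])
        with pytest.raises(ValueError, match="region"):
            om.fit_mbg(obs, grid, spec=ModelSpec(region=0, hyper=HyperGrid((0.5,), (3.0,), (0.5,), (0.02,))))

    def test_region_fits_independent(self, small_world):
        """Region-0 fit is bit-identical no matter what region-1 data exist."""
        obs = small_world.observations
        ors = obs[obs["indicator"] == "ORS"].reset_index(drop=True)
        from ortmap.pipeline import _record_region

        rr = _record_region(ors, small_world.grid)
        obs0 = ors[rr == 0].reset_index(drop=True)
        spec = ModelSpec(region=0, hyper=HyperGrid((0.5,), (3.0,), (0.5,), (0.02,)))
        f1 = om.fit_mbg(obs0, small_world.grid, pop=small_world.population, spec=spec)
        f2 = om.fit_mbg(obs0, small_world.grid, pop=small_world.population, spec=spec)
        for c1, c2 in zip(f1.components, f2.components):
            assert np.array_equal(c1.mode, c2.mode) and c1.weight == c2.weight


class TestDraws:
    def test_draw_count_and_range(self, small_fit):
        cube = om.draw_posterior_surfaces(small_fit, n_draws=250, seed=5)
        assert cube.p_draws.shape[0] == 250
        assert np.all(np.isfinite(cube.p_draws))
        assert np.all((cube.p_draws > 0) & (cube.p_draws < 1))

    def test_seeded_determinism(self, small_fit):
        a = om.draw_posterior_surfaces(small_fit, n_draws=20, seed=3)
        b = om.draw_posterior_surfaces(small_fit, n_draws=20, seed=3)
        assert np.array_equal(a.p_draws, b.p_draws)
        c = om.draw_posterior_surfaces(small_fit, n_draws=20, seed=4)
        assert not np.array_equal(a.p_draws, c.p_draws)

    def test_too_few_draws_errors(self, small_fit):
        with pytest.raises(ValueError):
            om.draw_posterior_surfaces(small_fit, n_draws=1, seed=0)

    def test_posterior_mean_tracks_observed_signal(self, small_world, small_fit):
        """The posterior mean surface correlates with the truth that generated
        the data (a sanity floor well below the pipeline-level requirement)."""
        cube = om.draw_posterior_surfaces(small_fit, n_draws=100, seed=1)
        est = cube.p_draws.mean(axis=0).ravel()
        truth = small_world.truths["ORS"].values[0].ravel()
        assert np.corrcoef(est, truth)[0, 1] > 0.3

    def test_merge_draw_cubes_partitions(self, small_world):
        obs = small_world.observations
        ors = obs[obs["indicator"] == "ORS"].reset_index(drop=True)
        from ortmap.pipeline import _record_region

        rr = _record_region(ors, small_world.grid)
        hyper = HyperGrid((0.5,), (3.0,), (0.5,), (0.02,))
        cubes = []
        for rg in (0, 1):
            f = om.fit_mbg(
                ors[rr == rg].reset_index(drop=True), small_world.grid,
                pop=small_world.population, spec=ModelSpec(region=rg, hyper=hyper),
            )
            cubes.append(om.draw_posterior_surfaces(f, n_draws=10, seed=rg))
        merged = om.merge_draw_cubes(cubes)
        assert merged.p_draws.shape == (10, small_world.grid.n_years, small_world.grid.n_cells)
        assert np.array_equal(np.sort(merged.cells), np.arange(small_world.grid.n_cells))
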