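import pytest

import ortmap as om


@pytest.fixture(scope="session")
def small_grid():
    return om.default_grid(12, 12, years=(2000, 2001, 2002), n_countries=3, n_regions=2)


@pytest.fixture(scope="session")
def small_world(small_grid):
    """One modest fully-populated world shared by read-only tests."""
    cfg = om.WorldConfig(
        n_rows=12,
        n_cols=12,
        years=(2000, 2001, 2002),
        design=om.SurveyDesign(n_surveys=9, clusters_per_survey=30),
    )
    return om.simulate_world(cfg, seed=42)


@pytest.fixture(scope="session")
def small_fit(small_world):
    """A fitted model on the small world's ORS records (points and polygons)."""
    obs = small_world.observations
    obs_ors = obs[obs["indicator"] == "ORS"].reset_index(drop=True)
    spec = om.ModelSpec(
        hyper=om.HyperGrid(
            sigma2_sp=(0.25, 1.0), range_sp=(3.0, 6.0), rho_t=(0.5, 0.9), tau2=(0.02,)
        )
    )
    return om.fit_mbg(obs_ors, small_world.grid, pop=small_world.population, spec=spec)
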