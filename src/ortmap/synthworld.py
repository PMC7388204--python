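"""Seeded synthetic worlds with the statistical structure the analysis assumes.

The generator emulates the data-generating process behind subnational
treatment-coverage surveys: logit-linear covariate effects plus a separable
space-time Gaussian field produce coverage surfaces; household-survey clusters
with small binomial denominators (children under 5 with diarrhoea) are sampled
proportional to population, as point- or polygon-referenced records; a share
of RHF records use a non-standard indicator definition (a logit offset);
ORS coverage trends up and RHF down by default; and diarrhoeal mortality is
negatively linked to ORS coverage by construction.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .cov import sample_separable_field
from .grid import GridSpec, RasterCube, default_grid

__all__ = [
    "TruthParams",
    "SurveyDesign",
    "MortalityLink",
    "WorldConfig",
    "World",
    "simulate_covariates",
    "simulate_population",
    "simulate_truth",
    "simulate_surveys",
    "simulate_mortality",
    "combine_ort",
    "simulate_world",
    "OBS_COLUMNS",
]

OBS_COLUMNS = [
    "survey_id",
    "year",
    "geo_type",
    "cell_id",
    "polygon_id",
    "N",
    "k",
    "indicator",
    "definition",
]


@dataclass
class TruthParams:
    """Parameters of the generative coverage model (logit scale)."""

    alpha: float = 0.0
    beta: np.ndarray | None = None
    sigma2_sp: float = 0.5
    range_sp: float = 6.0
    rho_t: float = 0.8
    tau2_nugget: float = 0.0225  # cluster-level nugget variance (sd 0.15)
    trend: float = 0.0  # annual logit drift

    def __post_init__(self):
        if self.sigma2_sp < 0 or self.tau2_nugget < 0:
            raise ValueError("variances must be nonnegative")
        if not (-1.0 < self.rho_t < 1.0):
            raise ValueError("|rho_t| must be < 1")
        if self.range_sp <= 0:
            raise ValueError("range_sp must be positive")


def default_truth_params(indicator: str, n_layers: int = 8) -> TruthParams:
    """Defaults emulating rising ORS and falling RHF coverage."""
    beta = np.zeros(n_layers)
    beta[: min(3, n_layers)] = [0.5, -0.35, 0.25][: min(3, n_layers)]
    trend = {"ORS": 0.08, "RHF": -0.08}.get(indicator, 0.0)
    alpha = {"ORS": -0.8, "RHF": -1.2}.get(indicator, -0.5)
    return TruthParams(alpha=alpha, beta=beta, trend=trend)


@dataclass
class SurveyDesign:
    """Survey sampling design: surveys of population-proportional clusters."""

    n_surveys: int = 18
    clusters_per_survey: int = 40
    mean_N: float = 10.0
    polygon_fraction: float = 0.1
    nonstandard_fraction: float = 0.3  # share of RHF surveys using the nonstandard definition
    dual_definition_fraction: float = 0.3  # share of nonstandard surveys also reporting standard
    defn_offset: float = -0.4  # logit-scale shift of the nonstandard definition
    nugget_sd: float = 0.15

    def __post_init__(self):
        if self.mean_N < 1:
            raise ValueError("mean_N must be >= 1")
        for f in ("polygon_fraction", "nonstandard_fraction", "dual_definition_fraction"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must be in [0,1]")


@dataclass
class MortalityLink:
    """Linear negative link between ORS coverage and the death rate."""

    base_rate: float = 0.004  # deaths per child-year absent any ORS coverage
    epsilon: float = 0.5  # fraction of deaths removed at full coverage
    noise_sd: float = 0.0  # lognormal multiplicative noise

    def __post_init__(self):
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must be in [0,1)")


def _smooth_field(rng, n_rows, n_cols, smooth=3.0):
    z = rng.standard_normal((n_rows, n_cols))
    f = gaussian_filter(z, sigma=smooth, mode="reflect")
    f = (f - f.mean()) / (f.std() + 1e-12)
    return f.ravel()


def simulate_covariates(
    grid: GridSpec, n_layers: int = 8, collinear_pairs: int = 1, seed: int = 0
) -> RasterCube:
    """Smooth standardized random covariate fields; the last ``collinear_pairs``
    layers are near-linear combinations of earlier layers (to exercise VIF
    filtering). Layers are static in time apart from a small smooth drift."""
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    if collinear_pairs >= n_layers:
        raise ValueError("collinear_pairs must be < n_layers")
    rng = np.random.default_rng(seed)
    n_indep = n_layers - collinear_pairs
    base = np.stack([_smooth_field(rng, grid.n_rows, grid.n_cols) for _ in range(n_indep)])
    layers = [f"cov{i:02d}" for i in range(n_layers)]
    fields = [base[i] for i in range(n_indep)]
    for j in range(collinear_pairs):
        a, b = rng.choice(n_indep, size=2, replace=False)
        combo = 0.7 * base[a] + 0.3 * base[b] + 0.05 * rng.standard_normal(grid.n_cells)
        fields.append(combo)
    values = np.empty((n_layers, grid.n_years, grid.n_cells))
    for i, f in enumerate(fields):
        drift = _smooth_field(rng, grid.n_rows, grid.n_cols)
        for t in range(grid.n_years):
            v = f + 0.05 * t * drift
            values[i, t] = (v - v.mean()) / (v.std() + 1e-12)
    return RasterCube(values, layers, grid)


def simulate_population(grid: GridSpec, seed: int = 0, mean_pop: float = 100.0) -> RasterCube:
    """Static under-5 population per cell (lognormal over a smooth field) plus a
    diarrhoea-episode layer (population x smooth prevalence in ~[0.15, 0.35])."""
    rng = np.random.default_rng(seed)
    f = _smooth_field(rng, grid.n_rows, grid.n_cols, smooth=4.0)
    pop_cell = mean_pop * np.exp(0.6 * f)
    prev_cell = 0.25 + 0.05 * _smooth_field(rng, grid.n_rows, grid.n_cols, smooth=4.0)
    prev_cell = np.clip(prev_cell, 0.05, 0.6)
    pop = np.tile(pop_cell, (grid.n_years, 1))
    episodes = np.tile(pop_cell * prev_cell, (grid.n_years, 1))
    return RasterCube(np.stack([pop, episodes]), ["population", "episodes"], grid)


def simulate_truth(
    grid: GridSpec,
    covs: RasterCube,
    params: TruthParams,
    indicator: str = "ORS",
    seed: int = 0,
) -> RasterCube:
    """Coverage surface p(cell, year) = invlogit(alpha + beta.x + trend*(year-y0)
    + GP), with the separable Matérn(3/2) x AR1 field."""
    beta = np.zeros(len(covs.layers)) if params.beta is None else np.asarray(params.beta, float)
    if beta.shape != (len(covs.layers),):
        raise ValueError(
            f"beta length {beta.shape} does not match {len(covs.layers)} covariate layers"
        )
    rng = np.random.default_rng(seed)
    gp = sample_separable_field(
        grid.cell_coords(), grid.n_years, params.sigma2_sp, params.range_sp, params.rho_t, rng
    )
    years = np.asarray(grid.years, float)
    eta = (
        params.alpha
        + np.einsum("l,lyc->yc", beta, covs.values)
        + params.trend * (years - years[0])[:, None]
        + gp
    )
    p = expit(eta)
    return RasterCube(p[None, :, :], [f"p_{indicator}"], grid)


def combine_ort(ors_truth: RasterCube, rhf_truth: RasterCube) -> RasterCube:
    """ORT = treatment with ORS, RHF, or both; union under independence, so
    ORT coverage dominates both components cell-wise."""
    p = 1.0 - (1.0 - ors_truth.values[0]) * (1.0 - rhf_truth.values[0])
    return RasterCube(p[None], ["p_ORT"], ors_truth.grid)


def _polygon_mean(p_year: np.ndarray, pop_year: np.ndarray, cells: np.ndarray) -> float:
    w = pop_year[cells]
    return float(np.sum(w * p_year[cells]) / np.sum(w))


def simulate_surveys(
    truth: RasterCube,
    pop: RasterCube,
    design: SurveyDesign,
    seed: int = 0,
    indicator: str = "ORS",
) -> pd.DataFrame:
    """Cluster-level survey records sampled from the truth surface.

    Surveys cycle over (country, year); cluster cells are drawn with
    probability proportional to population within the country. Point records
    draw k ~ Binomial(N, p_cell); polygon records reference an admin1 unit and
    use the population-weighted mean coverage over its cells. Cluster
    denominators are N = 1 + Poisson(mean_N - 1), guaranteeing N >= 1.

    For RHF, a ``nonstandard_fraction`` of surveys report under a non-standard
    definition (logit shift ``defn_offset``); a ``dual_definition_fraction`` of
    those additionally report the same clusters under the standard definition,
    providing calibration overlap for the crosswalk.
    """
    grid = truth.grid
    p_surface = truth.values[0]  # (n_years, n_cells)
    pop_vals = pop.layer("population")
    if np.any(pop_vals < 0):
        raise ValueError("population must be nonnegative")
    if pop_vals.sum() <= 0:
        raise ValueError("zero total population")
    rng = np.random.default_rng(seed)
    countries = grid.units("country")
    rows = []
    n_nonstd = int(round(design.nonstandard_fraction * design.n_surveys))
    use_nonstd = np.zeros(design.n_surveys, dtype=bool)
    use_dual = np.zeros(design.n_surveys, dtype=bool)
    if indicator == "RHF" and n_nonstd:
        nonstd_ids = rng.choice(design.n_surveys, size=n_nonstd, replace=False)
        use_nonstd[nonstd_ids] = True
        n_dual = int(np.ceil(design.dual_definition_fraction * n_nonstd))
        if n_dual:
            use_dual[rng.choice(nonstd_ids, size=n_dual, replace=False)] = True
    for s in range(design.n_surveys):
        country = countries[s % len(countries)]
        year_idx = (s // len(countries)) % grid.n_years
        year = grid.years[year_idx]
        cells = grid.cells_of("country", country)
        w = pop_vals[year_idx, cells]
        if w.sum() <= 0:
            raise ValueError(f"zero population in country {country}")
        probs = w / w.sum()
        nonstd = bool(use_nonstd[s])
        dual = bool(use_dual[s])
        admin1_units = np.unique(grid.admin1_of_cell[cells])
        for _ in range(design.clusters_per_survey):
            N = 1 + rng.poisson(design.mean_N - 1.0)
            nug = rng.normal(0.0, design.nugget_sd) if design.nugget_sd > 0 else 0.0
            if rng.random() < design.polygon_fraction:
                a1 = rng.choice(admin1_units)
                members = grid.cells_of("admin1", a1)
                p_base = _polygon_mean(p_surface[year_idx], pop_vals[year_idx], members)
                geo_type, cell_id, poly_id = "polygon", -1, int(a1)
            else:
                cell = int(rng.choice(cells, p=probs))
                p_base = p_surface[year_idx, cell]
                geo_type, cell_id, poly_id = "point", cell, -1
            eta = logit(np.clip(p_base, 1e-12, 1 - 1e-12)) + nug
            defs = []
            if nonstd:
                defs.append(("nonstandard", expit(eta + design.defn_offset)))
                if dual:
                    defs.append(("standard", expit(eta)))
            else:
                defs.append(("standard", expit(eta)))
            for definition, p_rec in defs:
                k = int(rng.binomial(N, p_rec))
                rows.append((s, year, geo_type, cell_id, poly_id, int(N), k, indicator, definition))
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def simulate_mortality(
    ors_truth: RasterCube, pop: RasterCube, link: MortalityLink | None = None, seed: int = 0
) -> RasterCube:
    """Diarrhoeal deaths per cell-year, negatively linked to ORS coverage:
    deaths = pop_u5 * base_rate * (1 - epsilon * coverage), with optional
    multiplicative lognormal noise."""
    link = link or MortalityLink()
    rng = np.random.default_rng(seed)
    p = ors_truth.values[0]
    pop_vals = pop.layer("population")
    deaths = pop_vals * link.base_rate * (1.0 - link.epsilon * p)
    if link.noise_sd > 0:
        deaths = deaths * np.exp(rng.normal(0.0, link.noise_sd, size=deaths.shape))
    return RasterCube(deaths[None], ["deaths"], ors_truth.grid)


@dataclass
class WorldConfig:
    """Full synthetic-world configuration (the study conditions)."""

    n_rows: int = 30
    n_cols: int = 30
    years: tuple = (2000, 2001, 2002, 2003, 2004, 2005)
    n_countries: int = 3
    n_regions: int = 2
    n_cov_layers: int = 8
    collinear_pairs: int = 1
    indicators: tuple = ("ORS", "RHF", "ORT")
    design: SurveyDesign = field(default_factory=SurveyDesign)
    mortality: MortalityLink = field(default_factory=MortalityLink)
    truth_overrides: dict = field(default_factory=dict)


@dataclass
class World:
    """A generated world: geography, inputs, truth surfaces, and observations."""

    grid: GridSpec
    covariates: RasterCube
    population: RasterCube
    truths: dict
    observations: pd.DataFrame
    mortality: RasterCube
    truth_params: dict


def simulate_world(config: WorldConfig | None = None, seed: int = 0) -> World:
    """Generate every input the pipeline consumes, deterministically."""
    config = config or WorldConfig()
    root = np.random.default_rng(seed)
    seeds = {k: int(root.integers(2**31)) for k in ("cov", "pop", "truth", "survey", "mort")}
    grid = default_grid(config.n_rows, config.n_cols, config.years, config.n_countries, config.n_regions)
    covs = simulate_covariates(grid, config.n_cov_layers, config.collinear_pairs, seeds["cov"])
    pop = simulate_population(grid, seeds["pop"])
    truths, params = {}, {}
    for i, ind in enumerate(ind for ind in config.indicators if ind != "ORT"):
        tp = config.truth_overrides.get(ind) or default_truth_params(ind, config.n_cov_layers)
        truths[ind] = simulate_truth(grid, covs, tp, ind, seeds["truth"] + i)
        params[ind] = tp
    if "ORT" in config.indicators:
        if {"ORS", "RHF"} <= truths.keys():
            truths["ORT"] = combine_ort(truths["ORS"], truths["RHF"])
        else:
            tp = config.truth_overrides.get("ORT") or default_truth_params("ORT", config.n_cov_layers)
            truths["ORT"] = simulate_truth(grid, covs, tp, "ORT", seeds["truth"] + 7)
            params["ORT"] = tp
    obs = pd.concat(
        [
            simulate_surveys(truths[ind], pop, config.design, seeds["survey"] + j, ind)
            for j, ind in enumerate(config.indicators)
        ],
        ignore_index=True,
    )
    mort = simulate_mortality(
        truths.get("ORS", next(iter(truths.values()))), pop, config.mortality, seeds["mort"]
    )
    return World(grid, covs, pop, truths, obs, mort, params)


def validate_observations(obs: pd.DataFrame) -> None:
    """Invariant checks on an observation table (0 <= k <= N, N >= 1, schema)."""
    missing = set(OBS_COLUMNS) - set(obs.columns)
    if missing:
        raise ValueError(f"observation table missing columns {sorted(missing)}")
    if (obs["N"] < 1).any():
        raise ValueError("N must be >= 1")
    if ((obs["k"] < 0) | (obs["k"] > obs["N"])).any():
        raise ValueError("k must satisfy 0 <= k <= N")
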