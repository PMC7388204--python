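"""Bayesian space-time geostatistical binomial model of treatment coverage.

The model: for survey record i with denominator N_i and numerator k_i,

    k_i ~ Binomial(N_i, p_i)
    logit p_i = alpha + s_i + u(cell_i, year_i)        (point records)
    p_i = population-weighted mean of p over member cells  (polygon records)

where ``s_i`` is the convex combination of stacked-learner logits (weights
non-negative, summing to one, fitted by constrained maximum likelihood on the
out-of-fold predictions) and ``u`` is a zero-mean Gaussian field with separable
Matérn(3/2)-in-space x AR1-in-time covariance plus an iid cell-year nugget.

Inference is an empirical-Bayes Laplace scheme: for each point of a coarse
hyperparameter grid (spatial variance, spatial range, temporal correlation,
nugget variance), the latent field at the observation sites is maximised and
Gaussian-approximated; grid points are mixed by their approximate marginal
posterior weights. Joint posterior surface draws are produced by sampling a
grid point, sampling the latent sites from the Gaussian approximation, and
conditionally simulating the field on the full grid (conditioning by kriging,
exploiting the Kronecker structure for the unconditional draw).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit, logsumexp
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .cov import ar1_corr, chol_corr, spatial_corr
from .grid import GridSpec, RasterCube
from .stacking import StackDesign

__all__ = [
    "HyperGrid",
    "ModelSpec",
    "PosteriorFit",
    "PosteriorDrawCube",
    "log_likelihood",
    "fit_mbg",
    "draw_posterior_surfaces",
    "predict_records",
    "merge_draw_cubes",
]

_ETA_CLIP = 35.0


# --------------------------------------------------------------------------
# configuration


@dataclass
class HyperGrid:
    """Coarse grid over (sigma2_sp, range_sp, rho_t, tau2_nugget)."""

    sigma2_sp: tuple = (0.25, 0.5, 1.0, 2.0)
    range_sp: tuple = (3.0, 6.0, 12.0)
    rho_t: tuple = (0.3, 0.5, 0.7, 0.9)
    tau2: tuple = (0.01, 0.05)

    def combos(self):
        return list(itertools.product(self.sigma2_sp, self.range_sp, self.rho_t, self.tau2))


@dataclass
class ModelSpec:
    """One model specification per region (regions are fitted independently)."""

    region: int | None = None
    hyper: HyperGrid = field(default_factory=HyperGrid)
    alpha_prior_sd: float = 10.0
    max_iter: int = 60
    tol: float = 1e-6
    # polygon records enter the latent field through at most this many member
    # cells (largest population first, weights renormalized); keeps the
    # Laplace dimension near the number of distinct point sites
    max_polygon_cells: int = 12

    def __post_init__(self):
        if self.alpha_prior_sd <= 0:
            raise ValueError("alpha prior sd must be positive (proper prior)")


def _log_hyperprior(theta):
    """Weakly-informative hyperpriors (documented defaults)."""
    sigma2, rng_sp, rho, tau2 = theta
    lp = norm.logpdf(np.log(sigma2), np.log(0.5), 1.5)
    lp += norm.logpdf(np.log(rng_sp), np.log(6.0), 1.0)
    lp += beta_dist.logpdf((rho + 1.0) / 2.0, 2.0, 2.0)
    lp += norm.logpdf(np.log(tau2), np.log(0.03), 1.5)
    return float(lp)


# --------------------------------------------------------------------------
# observation preprocessing


@dataclass
class _ObsData:
    """Observations mapped onto latent sites (unique cell-year pairs)."""

    site_cell: np.ndarray  # local cell index per site
    site_time: np.ndarray  # year index per site
    pt_site: np.ndarray  # site index per point record
    pt_N: np.ndarray
    pt_k: np.ndarray
    pt_s: np.ndarray  # stacker offset per point record
    polys: list  # (member site indices, weights, N, k, s_offset)
    n_sites: int = 0
    logpmf_const: float = 0.0

    def __post_init__(self):
        self.n_sites = len(self.site_cell)


def _prepare_obs(obs, grid, pop, cells, cell_pos, s_obs, max_polygon_cells=12):
    """Map records to latent sites restricted to the ``cells`` subset."""
    site_key = {}
    site_cell, site_time = [], []

    def site_of(local_cell, t):
        key = (local_cell, t)
        if key not in site_key:
            site_key[key] = len(site_cell)
            site_cell.append(local_cell)
            site_time.append(t)
        return site_key[key]

    pt_site, pt_N, pt_k, pt_s, polys = [], [], [], [], []
    pop_vals = pop.layer("population") if pop is not None else None
    for i, rec in enumerate(obs.itertuples(index=False)):
        t = grid.years.index(rec.year)
        s_i = float(s_obs[i]) if s_obs is not None else 0.0
        if rec.geo_type == "point":
            if rec.cell_id not in cell_pos:
                raise ValueError(f"record references cell {rec.cell_id} outside the model region")
            pt_site.append(site_of(cell_pos[rec.cell_id], t))
            pt_N.append(rec.N)
            pt_k.append(rec.k)
            pt_s.append(s_i)
        else:
            members = grid.cells_of("admin1", rec.polygon_id)
            members = members[np.isin(members, cells)]
            if members.size == 0:
                raise ValueError(f"polygon {rec.polygon_id} has no cells in the model region")
            if pop_vals is None:
                w = np.full(members.size, 1.0 / members.size)
            else:
                w = pop_vals[t, members]
                if w.sum() <= 0:
                    raise ValueError(f"polygon {rec.polygon_id} has zero population")
                w = w / w.sum()
            if members.size > max_polygon_cells:
                top = np.argsort(-w, kind="stable")[:max_polygon_cells]
                members, w = members[top], w[top] / w[top].sum()
            idx = np.array([site_of(cell_pos[c], t) for c in members])
            polys.append((idx, w, float(rec.N), float(rec.k), s_i))
    pt_N = np.asarray(pt_N, float)
    pt_k = np.asarray(pt_k, float)
    const = float(
        np.sum(gammaln(pt_N + 1) - gammaln(pt_k + 1) - gammaln(pt_N - pt_k + 1))
    ) + float(
        sum(gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1) for _, _, N, k, _ in polys)
    )
    return _ObsData(
        site_cell=np.asarray(site_cell, int),
        site_time=np.asarray(site_time, int),
        pt_site=np.asarray(pt_site, int),
        pt_N=pt_N,
        pt_k=pt_k,
        pt_s=np.asarray(pt_s, float),
        polys=polys,
        logpmf_const=const,
    )


# --------------------------------------------------------------------------
# likelihood


def log_likelihood(p_surface: np.ndarray, obs: pd.DataFrame, grid: GridSpec, pop=None) -> float:
    """Binomial log-likelihood of an observation set under a coverage surface.

    ``p_surface`` is (n_years, n_cells) on the probability scale. Point records
    use p at their cell-year; polygon records use the population-weighted mean
    of p over the polygon's member cells (equal weights if ``pop`` is None).
    """
    p_surface = np.asarray(p_surface, float)
    if p_surface.shape != (grid.n_years, grid.n_cells):
        raise ValueError("surface shape must be (n_years, n_cells)")
    pop_vals = pop.layer("population") if pop is not None else None
    total = 0.0
    for rec in obs.itertuples(index=False):
        t = grid.years.index(rec.year)
        if rec.geo_type == "point":
            if not 0 <= rec.cell_id < grid.n_cells:
                raise ValueError(f"record references missing cell {rec.cell_id}")
            p = p_surface[t, rec.cell_id]
        else:
            members = grid.cells_of("admin1", rec.polygon_id)
            if members.size == 0:
                raise ValueError(f"polygon {rec.polygon_id} resolves to no cells")
            if pop_vals is None:
                p = float(p_surface[t, members].mean())
            else:
                w = pop_vals[t, members]
                p = float(np.sum(w * p_surface[t, members]) / np.sum(w))
        p = min(max(p, 1e-12), 1.0 - 1e-12)
        total += (
            gammaln(rec.N + 1)
            - gammaln(rec.k + 1)
            - gammaln(rec.N - rec.k + 1)
            + rec.k * np.log(p)
            + (rec.N - rec.k) * np.log1p(-p)
        )
    return float(total)


def _ll_grad_hess(x, data: _ObsData, want_hess=True):
    """Log-likelihood, gradient, and negative Hessian in x = [alpha, u]."""
    n = 1 + data.n_sites
    alpha, u = x[0], x[1:]
    ll = data.logpmf_const
    g = np.zeros(n)
    W = np.zeros((n, n)) if want_hess else None

    if data.pt_site.size:
        eta = np.clip(alpha + data.pt_s + u[data.pt_site], -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        ll += float(np.sum(data.pt_k * np.log(mu) + (data.pt_N - data.pt_k) * np.log1p(-mu)))
        ge = data.pt_k - data.pt_N * mu
        g[0] += ge.sum()
        np.add.at(g, 1 + data.pt_site, ge)
        if want_hess:
            d = data.pt_N * mu * (1.0 - mu)
            d_site = np.bincount(data.pt_site, weights=d, minlength=data.n_sites)
            W[0, 0] += d.sum()
            W[0, 1:] += d_site
            W[1:, 0] += d_site
            W[1 + np.arange(data.n_sites), 1 + np.arange(data.n_sites)] += d_site

    for idx, w, N, k, s_i in data.polys:
        sig = expit(np.clip(alpha + s_i + u[idx], -_ETA_CLIP, _ETA_CLIP))
        p = float(np.clip(np.sum(w * sig), 1e-12, 1.0 - 1e-12))
        ll += k * np.log(p) + (N - k) * np.log1p(-p)
        dldp = k / p - (N - k) / (1.0 - p)
        d2ldp2 = -k / p**2 - (N - k) / (1.0 - p) ** 2
        q = w * sig * (1.0 - sig)  # dp/du_c
        jidx = np.concatenate(([0], 1 + idx))
        ghat = np.concatenate(([q.sum()], q))
        g[jidx] += dldp * ghat
        if want_hess:
            # Gauss-Newton block (the curvature-through-p term), PSD by construction
            W[np.ix_(jidx, jidx)] += (-d2ldp2) * np.outer(ghat, ghat)
    return ll, g, W


# --------------------------------------------------------------------------
# Laplace fit per hyperparameter combination


@dataclass
class _Component:
    theta: tuple
    mode: np.ndarray
    weight: float
    logml: float
    alpha_sd: float
    converged: bool
    grad_norm: float


@dataclass
class PosteriorFit:
    """Mixture-of-Laplace posterior over the hyperparameter grid."""

    components: list
    data: _ObsData
    cells: np.ndarray  # global cell ids covered by this fit
    coords: np.ndarray  # local cell coordinates
    n_years: int
    years: tuple
    grid: GridSpec
    spec: ModelSpec
    stack_weights: np.ndarray | None
    stack_names: list | None
    s_grid: np.ndarray  # (n_years, n_local_cells) stacker offset on the grid
    diagnostics: dict

    def hyper_posterior(self) -> pd.DataFrame:
        rows = [
            {
                "sigma2_sp": c.theta[0],
                "range_sp": c.theta[1],
                "rho_t": c.theta[2],
                "tau2": c.theta[3],
                "weight": c.weight,
                "alpha_mode": c.mode[0],
                "converged": c.converged,
            }
            for c in self.components
        ]
        return pd.DataFrame(rows)

    def sample_parameters(self, n: int, seed: int = 0) -> pd.DataFrame:
        """Posterior samples of (alpha, hyperparameters) by mixing the grid
        components; alpha uses each component's Gaussian marginal."""
        rng = np.random.default_rng(seed)
        weights = np.array([c.weight for c in self.components])
        idx = rng.choice(len(self.components), size=n, p=weights)
        rows = []
        for i in idx:
            c = self.components[i]
            rows.append(
                {
                    "alpha": rng.normal(c.mode[0], c.alpha_sd),
                    "sigma2_sp": c.theta[0],
                    "range_sp": c.theta[1],
                    "rho_t": c.theta[2],
                    "tau2": c.theta[3],
                }
            )
        return pd.DataFrame(rows)


def _site_cov(data, coords, n_years, theta):
    sigma2, rng_sp, rho, tau2 = theta
    R_s = spatial_corr(coords, rng_sp)
    R_t = ar1_corr(n_years, rho)
    S = sigma2 * R_s[np.ix_(data.site_cell, data.site_cell)] * R_t[
        np.ix_(data.site_time, data.site_time)
    ]
    S[np.diag_indices_from(S)] += tau2 + 1e-8
    return S


def _laplace_one(theta, data, coords, n_years, spec, x0):
    m = data.n_sites
    S = _site_cov(data, coords, n_years, theta)
    cS = cho_factor(S, lower=True)
    logdet_S = 2.0 * float(np.sum(np.log(np.diag(cS[0]))))
    Q_u = cho_solve(cS, np.eye(m))
    q_alpha = 1.0 / spec.alpha_prior_sd**2
    logdet_Q = -logdet_S - 2.0 * np.log(spec.alpha_prior_sd)

    def q_dot(x):
        out = np.empty_like(x)
        out[0] = q_alpha * x[0]
        out[1:] = Q_u @ x[1:]
        return out

    def objective(x):
        ll, _, _ = _ll_grad_hess(x, data, want_hess=False)
        return ll - 0.5 * float(x @ q_dot(x))

    x = x0.copy()
    obj = objective(x)
    converged = False
    grad_norm = np.inf
    cH = None
    for _ in range(spec.max_iter):
        ll, g, W = _ll_grad_hess(x, data)
        grad = g - q_dot(x)
        grad_norm = float(np.max(np.abs(grad)))
        H = W
        H[0, 0] += q_alpha
        H[1:, 1:] += Q_u
        cH = cho_factor(H, lower=True)
        if grad_norm < 1e-5:
            converged = True
            break
        step = cho_solve(cH, grad)
        t = 1.0
        for _ in range(30):
            x_new = x + t * step
            obj_new = objective(x_new)
            if obj_new >= obj - 1e-12:
                break
            t *= 0.5
        else:  # pragma: no cover - pathological
            break
        if abs(obj_new - obj) < spec.tol * (1.0 + abs(obj)):
            x, obj = x_new, obj_new
            ll, g, W = _ll_grad_hess(x, data)
            grad = g - q_dot(x)
            grad_norm = float(np.max(np.abs(grad)))
            H = W
            H[0, 0] += q_alpha
            H[1:, 1:] += Q_u
            cH = cho_factor(H, lower=True)
            converged = True
            break
        x, obj = x_new, obj_new
    ll, _, _ = _ll_grad_hess(x, data, want_hess=False)
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(cH[0]))))
    logml = (
        ll
        - 0.5 * float(x @ q_dot(x))
        + 0.5 * logdet_Q
        - 0.5 * logdet_H
        + _log_hyperprior(theta)
    )
    e0 = np.zeros(1 + m)
    e0[0] = 1.0
    alpha_var = float(cho_solve(cH, e0)[0])
    return x, logml, np.sqrt(max(alpha_var, 1e-12)), converged, grad_norm


def _fit_stack_weights(design: StackDesign, obs: pd.DataFrame) -> np.ndarray:
    """Convex-combination stacking weights by constrained binomial ML."""
    Z = design.obs_matrix
    k = obs["k"].to_numpy(float)
    N = obs["N"].to_numpy(float)
    L = Z.shape[1]

    def nll(w):
        p = expit(np.clip(Z @ w, -_ETA_CLIP, _ETA_CLIP))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(k * np.log(p) + (N - k) * np.log1p(-p)))

    res = minimize(
        nll,
        np.full(L, 1.0 / L),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * L,
        constraints=[{"type": "eq", "fun": lambda w: np.sum(w) - 1.0}],
    )
    w = np.clip(res.x, 0.0, 1.0)
    return w / w.sum()


def fit_mbg(
    obs: pd.DataFrame,
    grid: GridSpec,
    pop: RasterCube | None = None,
    design: StackDesign | None = None,
    spec: ModelSpec | None = None,
) -> PosteriorFit:
    """Fit the geostatistical binomial model by the Laplace grid scheme.

    ``spec.region`` restricts the fit (and later prediction) to the cells of
    one modelling region; observations must lie inside it. The fit is
    deterministic given its inputs.
    """
    if len(obs) == 0:
        raise ValueError("empty observation set")
    spec = spec or ModelSpec()
    if spec.region is None:
        cells = np.arange(grid.n_cells)
    else:
        cells = np.flatnonzero(grid.region_of_cell == spec.region)
        if cells.size == 0:
            raise ValueError(f"region {spec.region} has no cells")
    cell_pos = {int(c): i for i, c in enumerate(cells)}
    coords = grid.cell_coords()[cells]

    if design is not None:
        stack_w = _fit_stack_weights(design, obs)
        s_obs = design.obs_matrix @ stack_w
        s_grid = np.einsum("l,lyc->yc", stack_w, design.grid_matrix[:, :, cells])
        stack_names = list(design.names)
    else:
        stack_w, stack_names = None, None
        s_obs = None
        s_grid = np.zeros((grid.n_years, cells.size))

    data = _prepare_obs(obs, grid, pop, cells, cell_pos, s_obs, spec.max_polygon_cells)

    # warm start at the pooled empirical logit
    k_tot = float(obs["k"].sum())
    n_tot = float(obs["N"].sum())
    alpha0 = float(logit((k_tot + 0.5) / (n_tot + 1.0)))
    if s_obs is not None:
        alpha0 -= float(np.mean(s_obs))
    x0 = np.zeros(1 + data.n_sites)
    x0[0] = alpha0

    combos = spec.hyper.combos()
    comps = []
    x_warm = x0
    for theta in combos:
        mode, logml, a_sd, conv, gnorm = _laplace_one(theta, data, coords, grid.n_years, spec, x_warm)
        comps.append(_Component(theta, mode, 0.0, logml, a_sd, conv, gnorm))
        x_warm = mode
    if not any(c.converged for c in comps):
        raise RuntimeError(
            "Laplace optimisation failed to converge for every hyperparameter "
            f"combination (max grad norms {[c.grad_norm for c in comps]})"
        )
    logmls = np.array([c.logml if c.converged else -np.inf for c in comps])
    w = np.exp(logmls - logsumexp(logmls))
    for c, wi in zip(comps, w):
        c.weight = float(wi)
    n_conv = sum(c.converged for c in comps)
    if n_conv < len(comps):
        warnings.warn(
            f"{len(comps) - n_conv} hyperparameter combinations failed to converge "
            "and were excluded from the mixture",
            stacklevel=2,
        )
    return PosteriorFit(
        components=comps,
        data=data,
        cells=cells,
        coords=coords,
        n_years=grid.n_years,
        years=grid.years,
        grid=grid,
        spec=spec,
        stack_weights=stack_w,
        stack_names=stack_names,
        s_grid=s_grid,
        diagnostics={"n_converged": n_conv, "n_components": len(comps)},
    )


# --------------------------------------------------------------------------
# posterior draws


@dataclass
class PosteriorDrawCube:
    """Joint posterior coverage draws, (draw, year, cell) over a cell subset."""

    p_draws: np.ndarray  # (n_draws, n_years, n_local_cells)
    cells: np.ndarray  # global cell ids
    grid: GridSpec

    def __post_init__(self):
        if self.p_draws.ndim != 3:
            raise ValueError("p_draws must be (n_draws, n_years, n_cells)")

    @property
    def n_draws(self) -> int:
        return self.p_draws.shape[0]

    def full_surface(self, fill=np.nan) -> np.ndarray:
        """(n_draws, n_years, grid.n_cells) with ``fill`` outside the subset."""
        out = np.full((self.n_draws, self.grid.n_years, self.grid.n_cells), fill)
        out[:, :, self.cells] = self.p_draws
        return out


class _ComponentSampler:
    """Per-component factors needed for conditional surface simulation."""

    def __init__(self, comp, fit):
        sigma2, rng_sp, rho, tau2 = comp.theta
        data = fit.data
        self.comp = comp
        self.sigma2, self.tau2 = sigma2, tau2
        self.R_s = spatial_corr(fit.coords, rng_sp)
        self.R_t = ar1_corr(fit.n_years, rho)
        self.L_s = chol_corr(self.R_s)
        self.L_t = chol_corr(self.R_t)
        S = _site_cov(data, fit.coords, fit.n_years, comp.theta)
        self.cS = cho_factor(S, lower=True)
        # cross-covariance between every (year, cell) and the sites
        n_cells = len(fit.coords)
        self.C_gs = (
            sigma2
            * self.R_t[:, data.site_time][:, None, :]
            * self.R_s[:, data.site_cell][None, :, :]
        ).reshape(fit.n_years * n_cells, data.n_sites)
        # posterior Gaussian factor for x = [alpha, u]
        _, _, W = _ll_grad_hess(comp.mode, data)
        W[0, 0] += 1.0 / fit.spec.alpha_prior_sd**2
        W[1:, 1:] += cho_solve(self.cS, np.eye(data.n_sites))
        self.L_H = np.linalg.cholesky(W)  # lower factor of the posterior precision

    def sample_eta(self, n_d, fit, rng):
        """``n_d`` joint draws of the linear predictor on the full grid,
        batched through BLAS: latent sites from the Gaussian approximation,
        then conditioning-by-kriging against an unconditional Kronecker
        simulation. Returns (n_d, n_years * n_cells)."""
        data = fit.data
        m = data.n_sites
        n_cells = len(fit.coords)
        z = rng.standard_normal((1 + m, n_d))
        x = self.comp.mode[:, None] + solve_triangular(self.L_H, z, lower=True, trans="T")
        alpha_d, u_d = x[0], x[1:]  # (n_d,), (m, n_d)
        zf = rng.standard_normal((n_d, fit.n_years, n_cells))
        f_star = np.sqrt(self.sigma2) * np.matmul(np.matmul(self.L_t, zf), self.L_s.T)
        u_star = f_star[:, data.site_time, data.site_cell].T + np.sqrt(
            self.tau2
        ) * rng.standard_normal((m, n_d))
        krige = cho_solve(self.cS, u_d - u_star)  # (m, n_d)
        f_cond = f_star.reshape(n_d, -1) + (self.C_gs @ krige).T
        return alpha_d[:, None] + fit.s_grid.reshape(-1)[None, :] + f_cond


def draw_posterior_surfaces(
    fit: PosteriorFit, n_draws: int = 250, seed: int = 0
) -> PosteriorDrawCube:
    """Draw ``n_draws`` joint coverage surfaces from the fitted posterior.

    Each draw samples a hyperparameter grid point (by posterior weight), then
    the latent sites from the component's Gaussian approximation, then a
    conditional simulation of the field over all grid cell-years; the linear
    predictor (intercept + stacker offset + field) maps through the inverse
    logit. Deterministic given the seed. The nugget is site-level observation
    noise and is not added to the predicted surface.
    """
    eta, _ = _draw_eta(fit, n_draws, seed)
    p = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    return PosteriorDrawCube(p, fit.cells.copy(), fit.grid)


def predict_records(
    fit: PosteriorFit,
    obs: pd.DataFrame,
    pop: RasterCube | None = None,
    n_draws: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Posterior draws of the record-level coverage probability for held-out
    records, (n_records, n_draws). Point records receive the site-level nugget
    in the predictive; polygon records use the weighted mean over member cells.
    """
    cube = _draw_eta(fit, n_draws=n_draws, seed=seed)
    eta_draws, nugget_sd = cube  # (n_draws, n_years, n_cells_local), per-draw tau
    grid = fit.grid
    cell_pos = {int(c): i for i, c in enumerate(fit.cells)}
    rng = np.random.default_rng(seed + 1)
    pop_vals = pop.layer("population") if pop is not None else None
    out = np.empty((len(obs), eta_draws.shape[0]))
    for i, rec in enumerate(obs.itertuples(index=False)):
        t = grid.years.index(rec.year)
        if rec.geo_type == "point":
            if rec.cell_id not in cell_pos:
                raise ValueError(f"record references cell {rec.cell_id} outside the fit")
            eta = eta_draws[:, t, cell_pos[rec.cell_id]]
            eta = eta + nugget_sd * rng.standard_normal(eta.shape)
            out[i] = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        else:
            members = grid.cells_of("admin1", rec.polygon_id)
            members = members[np.isin(members, fit.cells)]
            idx = [cell_pos[int(c)] for c in members]
            p_mem = expit(np.clip(eta_draws[:, t, idx], -_ETA_CLIP, _ETA_CLIP))
            if pop_vals is None:
                out[i] = p_mem.mean(axis=1)
            else:
                w = pop_vals[t, members]
                out[i] = p_mem @ (w / w.sum())
    return out


def _draw_eta(fit, n_draws, seed):
    """Linear-predictor draws (n_draws, n_years, n_cells) plus per-draw
    nugget sd, sampling hyperparameter components by posterior weight."""
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    rng = np.random.default_rng(seed)
    weights = np.array([c.weight for c in fit.components])
    comp_idx = rng.choice(len(fit.components), size=n_draws, p=weights)
    n_cells = len(fit.coords)
    out = np.empty((n_draws, fit.n_years, n_cells))
    taus = np.empty(n_draws)
    for ci in np.unique(comp_idx):
        smp = _ComponentSampler(fit.components[int(ci)], fit)
        pos = np.flatnonzero(comp_idx == ci)
        eta = smp.sample_eta(len(pos), fit, rng)
        out[pos] = eta.reshape(len(pos), fit.n_years, n_cells)
        taus[pos] = np.sqrt(smp.tau2)
    return out, taus


def merge_draw_cubes(cubes: list) -> PosteriorDrawCube:
    """Stitch per-region draw cubes (disjoint cell subsets) into one cube."""
    if not cubes:
        raise ValueError("no cubes to merge")
    grid = cubes[0].grid
    n_draws = cubes[0].n_draws
    all_cells = np.concatenate([c.cells for c in cubes])
    if len(np.unique(all_cells)) != len(all_cells):
        raise ValueError("cubes overlap in cells")
    order = np.argsort(all_cells)
    p = np.concatenate([c.p_draws for c in cubes], axis=2)[:, :, order]
    return PosteriorDrawCube(p, all_cells[order], grid)
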