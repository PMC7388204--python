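"""Separable space-time covariance: Matérn(3/2) in space x AR1 in time.

Used both by the generative side (sampling truth surfaces) and the inference
side (the latent-field prior), so the fitted model class matches the simulated
one. Correlation matrices are unit-variance; the marginal variance multiplies
the Kronecker product.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

_JITTER = 1e-8


def matern32_corr(dist: np.ndarray, range_: float) -> np.ndarray:
    """Matérn correlation with smoothness 3/2 and spatial range parameter
    ``range_`` (the distance at which correlation drops to ~0.1 is ~2*range)."""
    if range_ <= 0:
        raise ValueError("range must be positive")
    s = np.sqrt(3.0) * np.asarray(dist) / range_
    return (1.0 + s) * np.exp(-s)


def ar1_corr(n_times: int, rho: float) -> np.ndarray:
    """Stationary AR1 correlation matrix rho^|t-t'| over consecutive steps."""
    if not (-1.0 < rho < 1.0):
        raise ValueError("|rho| must be < 1")
    lags = np.abs(np.subtract.outer(np.arange(n_times), np.arange(n_times)))
    return rho ** lags


def spatial_corr(coords: np.ndarray, range_: float) -> np.ndarray:
    return matern32_corr(cdist(coords, coords), range_)


def chol_corr(corr: np.ndarray) -> np.ndarray:
    """Cholesky factor with a small diagonal jitter for numerical safety."""
    n = corr.shape[0]
    return np.linalg.cholesky(corr + _JITTER * np.eye(n))


def sample_separable_field(
    coords: np.ndarray,
    n_times: int,
    sigma2: float,
    range_: float,
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One draw of the zero-mean separable GP; returns (n_times, n_cells).

    Exploits the Kronecker structure: if ``L_s`` and ``L_t`` are Cholesky
    factors of the spatial and temporal correlations, then ``L_t Z L_s^T``
    with iid standard-normal Z has covariance ``R_t (x) R_s``.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    n_cells = coords.shape[0]
    if sigma2 == 0:
        return np.zeros((n_times, n_cells))
    L_s = chol_corr(spatial_corr(coords, range_))
    L_t = chol_corr(ar1_corr(n_times, rho))
    z = rng.standard_normal((n_times, n_cells))
    return np.sqrt(sigma2) * (L_t @ z @ L_s.T)


def space_time_cov(
    coords: np.ndarray,
    time_idx: np.ndarray,
    sites_cell: np.ndarray,
    sigma2: float,
    range_: float,
    rho: float,
    n_times: int,
    other_cell: np.ndarray | None = None,
    other_time: np.ndarray | None = None,
) -> np.ndarray:
    """Dense covariance between site lists (cell index, time index pairs)."""
    R_s = spatial_corr(coords, range_)
    R_t = ar1_corr(n_times, rho)
    oc = sites_cell if other_cell is None else other_cell
    ot = time_idx if other_time is None else other_time
    return sigma2 * R_s[np.ix_(sites_cell, oc)] * R_t[np.ix_(time_idx, ot)]
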