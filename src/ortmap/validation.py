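"""Five-fold, admin2-blocked cross-validation of the fitted model.

Holdout sets combine randomised sets of records blocked at the second
administrative level: all records of an admin2 unit share a fold. Performance
is summarised per fold and pooled by bias (mean error), RMSE, 95% data
coverage within posterior-predictive intervals, and the Pearson correlation
between observed proportions and predicted means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec, RasterCube
from .mbg import ModelSpec, fit_mbg, predict_records

__all__ = ["CvReport", "make_folds", "cv_metrics", "cross_validate"]


def _record_admin2(obs: pd.DataFrame, grid: GridSpec) -> np.ndarray:
    """Blocking unit per record; polygon records take the smallest admin2 id
    inside their polygon (deterministic)."""
    out = np.empty(len(obs), dtype=int)
    for i, rec in enumerate(obs.itertuples(index=False)):
        if rec.geo_type == "point":
            out[i] = grid.admin2_of_cell[rec.cell_id]
        else:
            cells = grid.cells_of("admin1", rec.polygon_id)
            out[i] = int(np.min(grid.admin2_of_cell[cells]))
    return out


def make_folds(obs: pd.DataFrame, grid: GridSpec, k: int = 5, seed: int = 0) -> np.ndarray:
    """Admin2-blocked fold assignment, balanced greedily by record count."""
    blocks = _record_admin2(obs, grid)
    units, counts = np.unique(blocks, return_counts=True)
    if len(units) < k:
        raise ValueError(f"need at least k={k} admin2 units with data, have {len(units)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(units))
    units, counts = units[perm], counts[perm]
    order = np.argsort(-counts, kind="stable")  # big blocks first, then greedy
    fold_sizes = np.zeros(k, dtype=int)
    unit_fold = {}
    for i in order:
        f = int(np.argmin(fold_sizes))
        unit_fold[int(units[i])] = f
        fold_sizes[f] += counts[i]
    return np.array([unit_fold[int(b)] for b in blocks])


@dataclass
class CvReport:
    per_fold: pd.DataFrame
    pooled: dict
    folds: np.ndarray


def cv_metrics(obs: pd.DataFrame, p_draws: np.ndarray, seed: int = 0) -> dict:
    """Held-out metrics from predictive draws of the record probability.

    residual = observed k/N - posterior mean p. coverage95 counts records
    whose k lies inside the 2.5-97.5 percentile interval of the binomial
    posterior-predictive (a k draw per p draw). Pearson r between k/N and the
    mean p is NaN-flagged when either side has zero variance.
    """
    if p_draws.shape[0] != len(obs):
        raise ValueError("need predictive draws for every held-out record")
    rng = np.random.default_rng(seed)
    N = obs["N"].to_numpy(float)
    k = obs["k"].to_numpy(float)
    obs_p = k / N
    pred_mean = p_draws.mean(axis=1)
    resid = obs_p - pred_mean
    bias = float(resid.mean())
    rmse = float(np.sqrt(np.mean(resid**2)))
    k_rep = rng.binomial(N[:, None].astype(int), p_draws)
    lo = np.percentile(k_rep, 2.5, axis=1)
    hi = np.percentile(k_rep, 97.5, axis=1)
    coverage = float(np.mean((k >= lo) & (k <= hi)))
    if obs_p.std() < 1e-15 or pred_mean.std() < 1e-15:
        r = np.nan
    else:
        r = float(np.corrcoef(obs_p, pred_mean)[0, 1])
    return {"bias": bias, "rmse": rmse, "coverage95": coverage, "pearson_r": r, "n": len(obs)}


def cross_validate(
    obs: pd.DataFrame,
    grid: GridSpec,
    pop: RasterCube,
    spec: ModelSpec | None = None,
    k: int = 5,
    seed: int = 0,
    n_draws: int = 100,
) -> CvReport:
    """Blocked k-fold CV: refit on each training split, predict the held-out
    records, and summarise metrics per fold and pooled."""
    folds = make_folds(obs, grid, k=k, seed=seed)
    rows = []
    all_resid2, all_resid, all_cov, all_obs, all_pred = [], [], [], [], []
    for f in range(k):
        train = obs[folds != f].reset_index(drop=True)
        test = obs[folds == f].reset_index(drop=True)
        if len(test) == 0:
            continue
        fit = fit_mbg(train, grid, pop=pop, spec=spec)
        p_draws = predict_records(fit, test, pop=pop, n_draws=n_draws, seed=seed + 100 + f)
        m = cv_metrics(test, p_draws, seed=seed + 200 + f)
        m["fold"] = f
        rows.append(m)
        N = test["N"].to_numpy(float)
        obs_p = test["k"].to_numpy(float) / N
        pred = p_draws.mean(axis=1)
        all_resid.extend(obs_p - pred)
        all_obs.extend(obs_p)
        all_pred.extend(pred)
        all_cov.append((m["coverage95"], len(test)))
    per_fold = pd.DataFrame(rows)
    resid = np.asarray(all_resid)
    cov_pooled = float(
        np.sum([c * n for c, n in all_cov]) / np.sum([n for _, n in all_cov])
    )
    pooled = {
        "bias": float(resid.mean()),
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "coverage95": cov_pooled,
        "pearson_r": float(np.corrcoef(all_obs, all_pred)[0, 1]),
        "n": int(resid.size),
    }
    return CvReport(per_fold=per_fold, pooled=pooled, folds=folds)
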