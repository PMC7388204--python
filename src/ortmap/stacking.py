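"""Stacked generalisation: flexible child learners whose cross-fitted (out-of-
fold) predictions become covariates for the geostatistical model.

Three learners of increasing flexibility are fitted to the binomial survey
records via empirical-logit working responses weighted by the denominator:

* ``ridge`` — penalized linear-in-covariates regression (penalty by internal CV);
* ``spline`` — smooth additive model on covariates and space-time coordinates;
* ``gbt`` — boosted shallow regression trees (depth 2, 200 rounds).

Each record's out-of-fold prediction never saw that record (5 folds at the
cluster level); each learner also predicts on the full raster. The convex
ensembling weights are fitted downstream (see :mod:`ortmap.mbg`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import RidgeCV
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

from .grid import RasterCube

__all__ = ["StackerBundle", "StackDesign", "fit_child_learners", "stack_design"]

_P_CLIP = 1e-4
_LOGIT_LO, _LOGIT_HI = logit(_P_CLIP), logit(1.0 - _P_CLIP)


@dataclass
class StackerBundle:
    learners: list
    oof: np.ndarray  # (n_records, n_learners), logit scale
    grid_pred: np.ndarray  # (n_learners, n_years, n_cells), logit scale
    folds: np.ndarray  # fold id per record
    seed: int
    k_folds: int = 5


@dataclass
class StackDesign:
    names: list
    obs_matrix: np.ndarray  # (n_records, n_learners) OOF logits
    grid_matrix: np.ndarray  # (n_learners, n_years, n_cells) logits


def record_features(obs: pd.DataFrame, covs: RasterCube) -> np.ndarray:
    """Covariates + (row, col, year) per record. Polygon records use the
    unweighted cell mean of covariates over the polygon and its centroid."""
    grid = covs.grid
    coords = grid.cell_coords()
    n_layers = len(covs.layers)
    X = np.empty((len(obs), n_layers + 3))
    for i, rec in enumerate(obs.itertuples(index=False)):
        t = grid.years.index(rec.year)
        if rec.geo_type == "point":
            cells = np.array([rec.cell_id])
        else:
            cells = grid.cells_of("admin1", rec.polygon_id)
            if cells.size == 0:
                raise ValueError(f"polygon {rec.polygon_id} resolves to no cells")
        X[i, :n_layers] = covs.values[:, t, cells].mean(axis=1)
        X[i, n_layers : n_layers + 2] = coords[cells].mean(axis=0)
        X[i, n_layers + 2] = rec.year
    return X


def grid_features(covs: RasterCube) -> np.ndarray:
    """Feature matrix for every (year, cell), ordered year-major."""
    grid = covs.grid
    coords = grid.cell_coords()
    blocks = []
    for t, year in enumerate(grid.years):
        b = np.column_stack(
            [covs.values[:, t, :].T, coords, np.full(grid.n_cells, year)]
        )
        blocks.append(b)
    return np.vstack(blocks)


def _make_learners(n_cov: int, seed: int):
    cov_cols = list(range(n_cov))
    all_cols = slice(None)

    def ridge_factory():
        return (
            make_pipeline(StandardScaler(), RidgeCV(alphas=np.logspace(-2, 3, 11))),
            cov_cols,
        )

    def spline_factory():
        return (
            make_pipeline(
                StandardScaler(),
                SplineTransformer(n_knots=5, degree=3),
                RidgeCV(alphas=np.logspace(-1, 4, 11)),
            ),
            all_cols,
        )

    def gbt_factory():
        # early stopping keeps the booster near the mean when there is no
        # covariate signal while leaving headroom for strong signals
        return (
            GradientBoostingRegressor(
                max_depth=2,
                n_estimators=200,
                learning_rate=0.05,
                min_samples_leaf=20,
                n_iter_no_change=10,
                validation_fraction=0.2,
                random_state=seed,
            ),
            all_cols,
        )

    return {"ridge": ridge_factory, "spline": spline_factory, "gbt": gbt_factory}


def _fit_predict(factory, X, y, w, X_list):
    model, cols = factory()
    Xs = X[:, cols] if isinstance(cols, list) else X
    if hasattr(model, "steps"):  # pipeline: pass weight to the final estimator
        final = model.steps[-1][0]
        model.fit(Xs, y, **{f"{final}__sample_weight": w})
    else:
        model.fit(Xs, y, sample_weight=w)
    preds = []
    for Xp in X_list:
        Xps = Xp[:, cols] if isinstance(cols, list) else Xp
        preds.append(np.clip(model.predict(Xps), _LOGIT_LO, _LOGIT_HI))
    return preds


def fit_child_learners(
    obs: pd.DataFrame, covs: RasterCube, k_folds: int = 5, seed: int = 0
) -> StackerBundle:
    """Cross-fit the child learners and predict on the full raster.

    A learner that fails to fit is dropped with a warning; if all fail, an
    error is raised. Predictions are clipped to the logit of [1e-4, 1-1e-4].
    """
    if len(obs) == 0:
        raise ValueError("empty observation set")
    if len(obs) < k_folds:
        raise ValueError(f"need at least k_folds={k_folds} records, have {len(obs)}")
    grid = covs.grid
    X = record_features(obs, covs)
    Xg = grid_features(covs)
    k_arr = obs["k"].to_numpy(float)
    N_arr = obs["N"].to_numpy(float)
    y = logit((k_arr + 0.5) / (N_arr + 1.0))
    w = N_arr
    folds = np.empty(len(obs), dtype=int)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    for f, (_, test_idx) in enumerate(splits):
        folds[test_idx] = f

    factories = _make_learners(len(covs.layers), seed)
    names, oof_cols, grid_preds = [], [], []
    for name, factory in factories.items():
        try:
            oof = np.empty(len(obs))
            for train_idx, test_idx in splits:
                (pred,) = _fit_predict(
                    factory, X[train_idx], y[train_idx], w[train_idx], [X[test_idx]]
                )
                oof[test_idx] = pred
            (gp,) = _fit_predict(factory, X, y, w, [Xg])
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"learner {name!r} failed and was dropped: {exc}", stacklevel=2)
            continue
        names.append(name)
        oof_cols.append(oof)
        grid_preds.append(gp.reshape(grid.n_years, grid.n_cells))
    if not names:
        raise ValueError("all child learners failed")
    return StackerBundle(
        learners=names,
        oof=np.column_stack(oof_cols),
        grid_pred=np.stack(grid_preds),
        folds=folds,
        seed=seed,
        k_folds=k_folds,
    )


def stack_design(bundle: StackerBundle) -> StackDesign:
    """Expose OOF predictions (observation rows) and full-data learner rasters
    (prediction grid) as the fixed-effect design, column order fixed."""
    if bundle.oof.shape[1] != len(bundle.learners):
        raise ValueError("bundle OOF width does not match learner count")
    if bundle.grid_pred.shape[0] != len(bundle.learners):
        raise ValueError("missing raster layer for a learner")
    if not np.all(np.isfinite(bundle.grid_pred)):
        raise ValueError("non-finite raster predictions")
    return StackDesign(
        names=list(bundle.learners),
        obs_matrix=bundle.oof.copy(),
        grid_matrix=bundle.grid_pred.copy(),
    )
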