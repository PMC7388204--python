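"""Multicollinearity filtering of covariate layers by variance inflation factor.

VIF_j = 1 / (1 - R^2_j), with R^2_j from regressing layer j on the others.
Filtering iteratively removes the single worst layer until all VIFs fall at or
below the threshold (default 3), independently within each modelling region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import RasterCube

__all__ = ["VifReport", "compute_vif", "vif_filter", "vif_filter_by_region"]

_INF = np.inf


@dataclass
class VifReport:
    vif: dict  # final VIF per retained layer
    retained: list
    removed: list = field(default_factory=list)  # in removal order
    threshold: float = 3.0
    region: int | None = None


def _check_matrix(X: np.ndarray, names):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D design matrix with >= 2 columns")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix must be finite")
    sd = X.std(axis=0)
    for j, s in enumerate(sd):
        if s < 1e-12:
            raise ValueError(f"constant column {names[j]!r} has undefined VIF")
    return (X - X.mean(axis=0)) / sd


def compute_vif(X: np.ndarray, names=None) -> np.ndarray:
    """Per-column VIF; exact collinearity yields an +inf sentinel."""
    names = list(names) if names is not None else [f"col{j}" for j in range(np.shape(X)[1])]
    Z = _check_matrix(X, names)
    n, p = Z.shape
    vif = np.empty(p)
    for j in range(p):
        others = np.delete(Z, j, axis=1)
        coef, res, rank, _ = np.linalg.lstsq(others, Z[:, j], rcond=None)
        ss_tot = float(Z[:, j] @ Z[:, j])
        resid = Z[:, j] - others @ coef
        r2 = 1.0 - float(resid @ resid) / ss_tot
        vif[j] = _INF if r2 > 1.0 - 1e-10 else 1.0 / (1.0 - r2)
    return vif


def vif_filter(X: np.ndarray, names=None, threshold: float = 3.0, region=None) -> VifReport:
    """Iterative greedy VIF filter: drop the highest-VIF column and recompute
    until all VIFs <= threshold. Ties break lexicographically by layer name.
    A single surviving column is assigned VIF 1 (nothing left to inflate it)."""
    X = np.asarray(X, dtype=float)
    names = list(names) if names is not None else [f"col{j}" for j in range(X.shape[1])]
    _check_matrix(X, names)  # validate up front
    keep = list(range(X.shape[1]))
    removed = []
    while True:
        if len(keep) == 0:
            raise ValueError("VIF filtering removed all columns")
        if len(keep) == 1:
            vif = np.array([1.0])
        else:
            vif = compute_vif(X[:, keep], [names[j] for j in keep])
        if np.all(vif <= threshold):
            break
        worst = np.max(vif)
        tied = [keep[i] for i in np.flatnonzero(vif == worst)]
        drop = min(tied, key=lambda j: names[j])
        removed.append(names[drop])
        keep.remove(drop)
    return VifReport(
        vif={names[j]: float(v) for j, v in zip(keep, vif)},
        retained=[names[j] for j in keep],
        removed=removed,
        threshold=threshold,
        region=region,
    )


def vif_filter_by_region(
    covs: RasterCube, threshold: float = 3.0
) -> dict:
    """Run the VIF filter separately within each modelling region, pooling
    cell-year values. Returns {region_id: VifReport}."""
    grid = covs.grid
    reports = {}
    for region in grid.units("region"):
        cells = np.flatnonzero(grid.region_of_cell == region)
        X = covs.values[:, :, cells].reshape(len(covs.layers), -1).T
        reports[int(region)] = vif_filter(X, covs.layers, threshold, region=int(region))
    return reports
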