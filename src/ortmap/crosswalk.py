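"""Crosswalk of non-standard RHF indicator definitions onto the standard one.

Surveys that report the same clusters under both the standard and a
non-standard definition provide calibration pairs. A weighted regression on
the logit scale, logit(p_standard) = intercept + slope * logit(p_nonstandard),
is fitted over paired survey-level proportions and then applied to every
non-standard record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = ["AdjustmentModel", "fit_definition_adjustment", "apply_adjustment"]


@dataclass
class AdjustmentModel:
    intercept: float
    slope: float
    n_calibration: int
    indicator: str = "RHF"

    def __post_init__(self):
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("adjustment coefficients must be finite")
        if self.n_calibration < 2:
            raise ValueError("need at least 2 calibration surveys")

    def adjust_probability(self, p: np.ndarray) -> np.ndarray:
        return expit(self.intercept + self.slope * logit(p))


def _empirical_logit(k, n):
    """Empirical logit with 0.5 continuity correction at the boundaries."""
    k = np.asarray(k, float)
    n = np.asarray(n, float)
    p = np.where((k <= 0) | (k >= n), (k + 0.5) / (n + 1.0), k / n)
    return logit(p)


def fit_definition_adjustment(obs: pd.DataFrame, indicator: str = "RHF") -> AdjustmentModel:
    """Fit the definition crosswalk from surveys reporting both definitions.

    Survey-level pooled proportions (sum k / sum N per definition) are paired;
    the regression is weighted by the pooled denominator. If the fitted slope
    is not positive (a non-monotone crosswalk), falls back with a warning to an
    offset-only model (slope fixed at 1).
    """
    sub = obs[obs["indicator"] == indicator]
    pooled = (
        sub.groupby(["survey_id", "definition"])[["k", "N"]].sum().reset_index()
    )
    wide = pooled.pivot(index="survey_id", columns="definition", values=["k", "N"])
    have_both = (
        "standard" in pooled["definition"].values
        and "nonstandard" in pooled["definition"].values
        and not wide.isna().any(axis=1).all()
    )
    if not have_both:
        raise ValueError("no calibration overlap: no surveys report both definitions")
    paired = wide.dropna()
    if len(paired) < 2:
        raise ValueError(
            f"no calibration overlap: need >=2 paired surveys, found {len(paired)}"
        )
    y = _empirical_logit(paired[("k", "standard")], paired[("N", "standard")])
    x = _empirical_logit(paired[("k", "nonstandard")], paired[("N", "nonstandard")])
    w = (paired[("N", "standard")] + paired[("N", "nonstandard")]).to_numpy(float)
    if np.var(x) < 1e-12:
        raise ValueError("degenerate fit: no variation in nonstandard proportions")
    W = np.diag(w)
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * y, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    if not np.all(np.isfinite([intercept, slope])):
        raise ValueError("degenerate fit: non-finite coefficients")
    if slope <= 0:
        warnings.warn(
            "fitted crosswalk slope not positive; falling back to offset-only model",
            stacklevel=2,
        )
        slope = 1.0
        intercept = float(np.average(y - x, weights=w))
    return AdjustmentModel(intercept, slope, n_calibration=len(paired), indicator=indicator)


def apply_adjustment(obs: pd.DataFrame, model: AdjustmentModel) -> pd.DataFrame:
    """Map every non-standard record of the model's indicator through the
    crosswalk on the logit scale; k is replaced by round(N * adjusted p),
    clamped to [0, N], and the definition tag becomes ``standard(adjusted)``."""
    out = obs.copy()
    mask = (out["indicator"] == model.indicator) & (out["definition"] == "nonstandard")
    if not mask.any():
        return out
    N = out.loc[mask, "N"].to_numpy(float)
    k = out.loc[mask, "k"].to_numpy(float)
    p_in = np.where((k <= 0) | (k >= N), (k + 0.5) / (N + 1.0), k / N)
    p_adj = model.adjust_probability(p_in)
    k_adj = np.clip(np.round(N * p_adj), 0, N).astype(int)
    out.loc[mask, "k"] = k_adj
    out.loc[mask, "definition"] = "standard(adjusted)"
    return out
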