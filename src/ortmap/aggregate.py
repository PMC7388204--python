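"""Population-weighted aggregation of posterior draw cubes to admin units,
uncertainty intervals, annualised rates of change, untreated-children counts,
and between-indicator trend correlations.

Uncertainty intervals are the 2.5th and 97.5th empirical percentiles of the
(by default 250) posterior draws, computed with the linear-interpolation
percentile rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit

from .grid import RasterCube
from .mbg import PosteriorDrawCube

__all__ = [
    "AdminAggregate",
    "ArocRecord",
    "aggregate_draws",
    "summarize_ui",
    "compute_aroc",
    "count_untreated",
    "proportion_below",
    "correlate_trends",
    "share_percent",
]

_P_CLIP = 1e-6


def share_percent(count: int, total: int, decimals: int = 1) -> float:
    """Reporting rule for printed shares: percentage rounded to ``decimals``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return float(np.round(100.0 * count / total, decimals))


def summarize_ui(draws: np.ndarray) -> tuple:
    """(mean, lower95, upper95) of a draw vector; percentiles by linear
    interpolation between order statistics."""
    draws = np.asarray(draws, float)
    if draws.size < 2:
        raise ValueError("need at least 2 draws")
    if np.isnan(draws).any():
        raise ValueError("NaN draws")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(draws.mean()), float(lo), float(hi)


@dataclass
class AdminAggregate:
    """Per (unit, year) draw values with population weights used."""

    draws: np.ndarray  # (n_units, n_years, n_draws)
    units: np.ndarray
    years: tuple
    level: str
    population: np.ndarray  # (n_units, n_years)

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, u in enumerate(self.units):
            for t, y in enumerate(self.years):
                mean, lo, hi = summarize_ui(self.draws[i, t])
                rows.append(
                    {
                        "unit_id": int(u),
                        "level": self.level,
                        "year": int(y),
                        "mean": mean,
                        "lower95": lo,
                        "upper95": hi,
                    }
                )
        return pd.DataFrame(rows)

    def mean_series(self) -> pd.DataFrame:
        """(unit x year) matrix of draw means."""
        return pd.DataFrame(
            self.draws.mean(axis=2), index=self.units, columns=list(self.years)
        )

    def year_index(self, year: int) -> int:
        return list(self.years).index(year)


def aggregate_draws(
    cube: PosteriorDrawCube, pop: RasterCube, level: str
) -> AdminAggregate:
    """Population-weighted aggregation of every draw to admin units.

    Per draw d and unit A: value = sum_i pop_i p_id / sum_i pop_i over member
    cells i. Units with zero population are excluded with a warning.
    """
    grid = cube.grid
    unit_map = grid.unit_map(level)[cube.cells]
    pop_vals = pop.layer("population")[:, cube.cells]  # (n_years, n_local)
    if np.any(pop_vals < 0):
        raise ValueError("population must be nonnegative")
    units = np.unique(unit_map)
    keep_units, agg, pops = [], [], []
    for u in units:
        mask = unit_map == u
        w = pop_vals[:, mask]  # (n_years, n_members)
        totals = w.sum(axis=1)
        if np.any(totals <= 0):
            warnings.warn(f"unit {u} has zero population; excluded", stacklevel=2)
            continue
        # (n_draws, n_years, n_members) . weights -> (n_draws, n_years)
        vals = np.einsum("dym,ym->dy", cube.p_draws[:, :, mask], w) / totals
        keep_units.append(u)
        agg.append(vals.T)  # (n_years, n_draws)
        pops.append(totals)
    if not keep_units:
        raise ValueError("no units with positive population")
    return AdminAggregate(
        draws=np.stack(agg),  # (n_units, n_years, n_draws)
        units=np.asarray(keep_units),
        years=grid.years,
        level=level,
        population=np.stack(pops),
    )


@dataclass
class ArocRecord:
    """Per-unit annualised rate of change draws and summaries (percent)."""

    units: np.ndarray
    draws: np.ndarray  # (n_units, n_draws)
    y0: int
    y1: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, u in enumerate(self.units):
            mean, lo, hi = summarize_ui(self.draws[i])
            rows.append(
                {
                    "unit_id": int(u),
                    "aroc_mean": mean,
                    "aroc_lower95": lo,
                    "aroc_upper95": hi,
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
        return pd.DataFrame(rows)


def compute_aroc(agg: AdminAggregate, y0: int, y1: int) -> ArocRecord:
    """AROC per draw on the logit scale, reported in percent:
    100 * (logit p_y1 - logit p_y0) / (y1 - y0). Probabilities at 0 or 1 are
    clipped to [1e-6, 1 - 1e-6] with a warning."""
    if y0 >= y1:
        raise ValueError("need y0 < y1")
    i0, i1 = agg.year_index(y0), agg.year_index(y1)
    p0 = agg.draws[:, i0, :]
    p1 = agg.draws[:, i1, :]
    if np.any((p0 <= 0) | (p0 >= 1) | (p1 <= 0) | (p1 >= 1)):
        warnings.warn("coverage draws at 0 or 1 clipped for AROC", stacklevel=2)
    p0 = np.clip(p0, _P_CLIP, 1 - _P_CLIP)
    p1 = np.clip(p1, _P_CLIP, 1 - _P_CLIP)
    aroc = 100.0 * (logit(p1) - logit(p0)) / (y1 - y0)
    return ArocRecord(units=agg.units.copy(), draws=aroc, y0=y0, y1=y1)


def count_untreated(
    cube: PosteriorDrawCube, episodes: RasterCube, level: str = "admin2"
) -> pd.DataFrame:
    """Children with diarrhoea not receiving the treatment, per unit and total.

    Per draw: untreated = sum over member cells of episodes * (1 - p). The
    episode raster is treated as fixed (no uncertainty attached). Returns one
    row per unit-year plus ``unit_id = -1`` totals, with mean and 95% UI.
    """
    grid = cube.grid
    epi = episodes.layer("episodes")[:, cube.cells]
    if np.any(epi < 0):
        raise ValueError("episodes raster must be nonnegative")
    unit_map = grid.unit_map(level)[cube.cells]
    rows = []
    totals = np.zeros((cube.n_draws, grid.n_years))
    for u in np.unique(unit_map):
        mask = unit_map == u
        vals = np.einsum("dym,ym->dy", 1.0 - cube.p_draws[:, :, mask], epi[:, mask])
        totals += vals
        for t, y in enumerate(grid.years):
            mean, lo, hi = summarize_ui(vals[:, t])
            rows.append(
                {"unit_id": int(u), "year": int(y), "mean": mean, "lower95": lo, "upper95": hi}
            )
    for t, y in enumerate(grid.years):
        mean, lo, hi = summarize_ui(totals[:, t])
        rows.append({"unit_id": -1, "year": int(y), "mean": mean, "lower95": lo, "upper95": hi})
    return pd.DataFrame(rows)


def proportion_below(agg: AdminAggregate, threshold: float, year: int) -> dict:
    """Share of units whose mean coverage is below ``threshold`` in ``year``;
    percentage rounded to one decimal for reporting."""
    if agg.draws.size == 0:
        raise ValueError("empty aggregate")
    t = agg.year_index(year)
    means = agg.draws[:, t, :].mean(axis=1)
    count = int(np.sum(means < threshold))
    total = int(means.size)
    return {"count": count, "total": total, "percent": share_percent(count, total, 1)}


def correlate_trends(series_a: pd.DataFrame, series_b: pd.DataFrame) -> dict:
    """Per-unit Pearson correlation over years between two mean time-series
    (unit x year frames from :meth:`AdminAggregate.mean_series`).

    Units with fewer than 3 common years are skipped with a warning; units
    with zero variance in either series are excluded from the share's
    denominator (their count is reported).
    """
    common_units = series_a.index.intersection(series_b.index)
    common_years = [y for y in series_a.columns if y in set(series_b.columns)]
    per_unit = {}
    n_skipped = 0
    if len(common_years) < 3:
        raise ValueError("need at least 3 common years")
    for u in common_units:
        a = series_a.loc[u, common_years].to_numpy(float)
        b = series_b.loc[u, common_years].to_numpy(float)
        if a.std() < 1e-15 or b.std() < 1e-15:
            n_skipped += 1
            per_unit[u] = np.nan
            continue
        per_unit[u] = float(np.corrcoef(a, b)[0, 1])
    r = pd.Series(per_unit, name="pearson_r")
    valid = r.dropna()
    n_negative = int((valid < 0).sum())
    return {
        "per_unit": r,
        "n_negative": n_negative,
        "n_valid": int(len(valid)),
        "n_zero_variance": n_skipped,
        "percent_negative": share_percent(n_negative, len(valid), 1) if len(valid) else np.nan,
    }
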