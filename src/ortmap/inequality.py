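"""Within-country geographical inequality metrics.

Three complementary measures over a country's second-administrative units:
the population-weighted Gini coefficient (0 = perfect equality, 1 = maximum
inequality), the absolute percentage-point deviation of each unit from the
country mean, and the relative deviation from the country mean (percent).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aggregate import AdminAggregate, share_percent

__all__ = ["gini", "deviation_from_mean", "country_inequality", "inequality_trends"]


def gini(values: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Population-weighted Gini coefficient.

    G = sum_ij w_i w_j |x_i - x_j| / (2 xbar) with weights normalized to sum
    one and xbar the weighted mean. Reduces to the classical unweighted form
    for equal weights; scale-invariant in the values.
    """
    x = np.asarray(values, float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if np.any(x < 0):
        raise ValueError("values must be nonnegative")
    if weights is None:
        w = np.full(x.size, 1.0 / x.size)
    else:
        w = np.asarray(weights, float)
        if w.shape != x.shape:
            raise ValueError("weights must match values")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        w = w / w.sum()
    xbar = float(np.sum(w * x))
    if xbar == 0:
        raise ValueError("all values zero: Gini undefined")
    # O(n log n) via sorted cumulative form of the pairwise sum
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    cxw = np.cumsum(xs * ws)
    # sum_i w_i [ x_i * F_{i-} - S_{i-} ] over pairs j < i, doubled
    mad = 2.0 * float(np.sum(ws * (xs * (cw - ws) - (cxw - xs * ws))))
    # G >= 0 analytically; cumulative sums can leave a ~1e-17 residue
    return max(mad / (2.0 * xbar), 0.0)


def deviation_from_mean(unit_values: np.ndarray, country_mean: float) -> pd.DataFrame:
    """Absolute (percentage-point) and relative (%) deviation from the
    country mean; relative deviation is undefined (NaN) for a zero mean."""
    x = np.asarray(unit_values, float)
    abs_dev = 100.0 * (x - country_mean)
    if country_mean > 0:
        rel_dev = 100.0 * (x - country_mean) / country_mean
    else:
        rel_dev = np.full_like(x, np.nan)
    return pd.DataFrame({"abs_dev_pp": abs_dev, "rel_dev_pct": rel_dev})


def country_inequality(agg: AdminAggregate, grid, year: int) -> pd.DataFrame:
    """Gini and deviations per country for one year, computed on draw means of
    admin2 aggregates weighted by unit population.

    Returns one row per (country, admin2) with the country's Gini repeated,
    plus the unit deviations.
    """
    if agg.level != "admin2":
        raise ValueError("inequality metrics are computed over admin2 aggregates")
    t = agg.year_index(year)
    means = agg.draws[:, t, :].mean(axis=1)
    pops = agg.population[:, t]
    # map admin2 -> country via the grid partition
    a2_to_country = {}
    for a2 in grid.units("admin2"):
        cells = grid.cells_of("admin2", a2)
        a2_to_country[int(a2)] = int(grid.country_of_cell[cells[0]])
    countries = np.array([a2_to_country[int(u)] for u in agg.units])
    rows = []
    for c in np.unique(countries):
        mask = countries == c
        w = pops[mask]
        x = means[mask]
        g = gini(x, w)
        cmean = float(np.sum(w * x) / w.sum())
        dev = deviation_from_mean(x, cmean)
        for u, ad, rd in zip(agg.units[mask], dev["abs_dev_pp"], dev["rel_dev_pct"]):
            rows.append(
                {
                    "country": int(c),
                    "admin2": int(u),
                    "year": int(year),
                    "gini": g,
                    "country_mean": cmean,
                    "abs_dev_pp": float(ad),
                    "rel_dev_pct": float(rd),
                }
            )
    return pd.DataFrame(rows)


def inequality_trends(records_y0: pd.DataFrame, records_y1: pd.DataFrame) -> dict:
    """Per-country change flags between two years and cross-country counts.

    Flags per country: Gini declined; absolute range (max-min abs deviation)
    declined; maximum relative deviation declined; any unit at >= 50% relative
    deviation in the later year. Percentages are integer-rounded for
    reporting.
    """
    c0 = set(records_y0["country"].unique())
    c1 = set(records_y1["country"].unique())
    if c0 != c1:
        raise ValueError("mismatched country sets between years")
    rows = []
    for c in sorted(c0):
        r0 = records_y0[records_y0["country"] == c]
        r1 = records_y1[records_y1["country"] == c]
        g0, g1 = float(r0["gini"].iloc[0]), float(r1["gini"].iloc[0])
        rng0 = float(r0["abs_dev_pp"].max() - r0["abs_dev_pp"].min())
        rng1 = float(r1["abs_dev_pp"].max() - r1["abs_dev_pp"].min())
        mrd0 = float(r0["rel_dev_pct"].abs().max())
        mrd1 = float(r1["rel_dev_pct"].abs().max())
        rows.append(
            {
                "country": int(c),
                "gini_declined": g1 < g0,
                "abs_range_declined": rng1 < rng0,
                "max_rel_dev_declined": mrd1 < mrd0,
                "rel_dev_ge_50": bool((r1["rel_dev_pct"].abs() >= 50.0).any()),
            }
        )
    flags = pd.DataFrame(rows)
    n = len(flags)
    summary = {"n_countries": n}
    for col in ("gini_declined", "abs_range_declined", "max_rel_dev_declined", "rel_dev_ge_50"):
        count = int(flags[col].sum())
        summary[col] = {"count": count, "percent": int(round(share_percent(count, n, 0)))}
    return {"flags": flags, "summary": summary}
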