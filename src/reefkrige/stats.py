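"""Downstream statistics on probability grids and thermal stress.

Covers the headline analyses of the occurrence maps: reef area exceeding
bleaching-probability thresholds (>50% "more likely than not", >66%
"likely", >90% "very likely"), reef-area-weighted mean/median annual
maximum DHW by probability class, fold changes between the 12-year periods
before (1985-1996) and after (1999-2010) the 1997/1998 El Nino, Welch
two-tailed t-tests for period and class contrasts, and the OLS trend of
area-weighted DHW over the record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Probability thresholds named after likelihood language.
THRESHOLDS = {"more_likely_than_not": 0.50, "likely": 0.66, "very_likely": 0.90}

#: Probability classes for thermal-stress statistics: (low, high], strict
#: lower bound and inclusive upper bound, None = unbounded.
PROBABILITY_CLASSES = {
    "all": (None, None),
    ">50-66%": (0.50, 0.66),
    ">66-90%": (0.66, 0.90),
    ">66%": (0.66, None),
    ">90%": (0.90, None),
}

EARLY_PERIOD = (1985, 1996)
LATE_PERIOD = (1999, 2010)


def threshold_area(probability: pd.Series, reef_area: pd.Series, tau: float) -> float:
    """Total reef area (km^2) of cells with probability strictly above tau."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    p, a = probability.align(reef_area, join="inner")
    return float(a[p > tau].sum())


def _class_mask(p: np.ndarray, cls: str) -> np.ndarray:
    if cls not in PROBABILITY_CLASSES:
        raise ValueError(f"unknown probability class {cls!r}")
    lo, hi = PROBABILITY_CLASSES[cls]
    m = np.ones(p.shape, dtype=bool)
    if lo is not None:
        m &= p > lo
    if hi is not None:
        m &= p <= hi
    return m


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Value at which cumulative weight first reaches half the total."""
    order = np.argsort(values, kind="stable")
    v, w = np.asarray(values, float)[order], np.asarray(weights, float)[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def weighted_dhw_stats(
    table: pd.DataFrame,
    cls: str = "all",
) -> Optional[tuple[float, float]]:
    """Reef-area-weighted mean and median annual max DHW for one class.

    ``table`` has one row per (cell, year) with columns ``probability``,
    ``dhw`` (annual maximum, degC-weeks) and ``reef_area`` (km^2); pooling
    is over all pairs, weighted by cell reef area.  Returns None for an
    empty class.
    """
    m = _class_mask(table["probability"].to_numpy(float), cls)
    sub = table.loc[m]
    if len(sub) == 0 or sub["reef_area"].sum() <= 0:
        return None
    w = sub["reef_area"].to_numpy(float)
    d = sub["dhw"].to_numpy(float)
    mean = float(np.average(d, weights=w))
    return mean, weighted_median(d, w)


def welch_t(a, b) -> tuple[float, float, float]:
    """Two-tailed t-test assuming unequal variances: (t, Welch df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("degenerate zero-variance samples with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def period_fold_change(
    series: pd.Series,
    early: tuple[int, int] = EARLY_PERIOD,
    late: tuple[int, int] = LATE_PERIOD,
) -> float:
    """mean(late period) / mean(early period) of a year-indexed series.

    Returns inf when the early mean is zero and the late mean positive
    (flagged, not an error); raises when either period has no years.
    """
    yrs = series.index.to_numpy()
    a = series[(yrs >= early[0]) & (yrs <= early[1])]
    b = series[(yrs >= late[0]) & (yrs <= late[1])]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty period")
    ma, mb = float(a.mean()), float(b.mean())
    if ma == 0.0:
        return float("inf") if mb > 0 else float("nan")
    return mb / ma


def linear_trend(series: pd.Series) -> tuple[float, float]:
    """OLS slope of value on year with two-sided p for slope != 0.

    A constant series returns (0.0, 1.0) by convention.
    """
    if len(series) < 3:
        raise ValueError("trend needs at least 3 years")
    y = series.to_numpy(float)
    x = series.index.to_numpy(float)
    if np.allclose(y, y[0]):
        return 0.0, 1.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.pvalue)


@dataclass
class AreaSeries:
    """Annual reef areas above each probability threshold (km^2)."""

    table: pd.DataFrame  # index year, one column per threshold name

    def fold_changes(self) -> dict:
        return {c: period_fold_change(self.table[c]) for c in self.table.columns}


def annual_threshold_areas(
    prob_grids: pd.DataFrame,
    grid,
    thresholds: dict = THRESHOLDS,
) -> AreaSeries:
    """Per-year exceedance areas from a long (cell_id, year, probability) frame."""
    areas = grid.cells["reef_area"]
    rows = {}
    for year, g in prob_grids.groupby("year"):
        p = g.set_index("cell_id")["probability"]
        rows[int(year)] = {name: threshold_area(p, areas, tau) for name, tau in thresholds.items()}
    tab = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    tab.index.name = "year"
    return AreaSeries(tab)


def dhw_probability_table(
    prob_grids: pd.DataFrame,
    annual_dhw: pd.DataFrame,
    grid,
) -> pd.DataFrame:
    """Pooled (cell, year) table joining probability, annual max DHW and area.

    ``annual_dhw`` is indexed by cell_id with one column per year.
    """
    long = annual_dhw.stack().rename("dhw").reset_index()
    long.columns = ["cell_id", "year", "dhw"]
    merged = prob_grids.merge(long, on=["cell_id", "year"], how="inner")
    merged["reef_area"] = grid.cells["reef_area"].reindex(merged["cell_id"]).to_numpy()
    return merged.dropna(subset=["dhw", "reef_area"])
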