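"""HotSpot and Degree Heating Week (DHW) thermal stress from SST series.

DHW accumulates, over a trailing 12-week (84-day) window, the positive SST
anomalies relative to the maximum monthly mean (MMM) climatology that are at
least 1 degC, expressed in degC-weeks:

    HotSpot(t) = max(0, SST(t) - MMM)
    DHW(t)     = sum over s in (t - 84 d, t] of HotSpot(s)/7 * days(s),
                 counting only HotSpot(s) >= 1 degC

where ``days(s)`` is the number of days each observation represents (1 for
daily series, 3.5 for twice-weekly Pathfinder-style series).  Both the
window length and the 1 degC accumulation threshold are parameters.

A reef cell counts as thermally stressed in a calendar year when its annual
maximum DHW exceeds 0 degC-weeks; the complement (annual max exactly zero)
defines the pseudo-absence cells of the occurrence model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

DHW_WINDOW_DAYS = 84.0
DHW_THRESHOLD_C = 1.0


def hotspot(sst, mmm):
    """Positive part of SST minus MMM, degC; NaN SST propagates to NaN."""
    sst = np.asarray(sst, dtype=float)
    mmm = np.asarray(mmm, dtype=float)
    out = np.maximum(sst - mmm, 0.0)
    return np.where(np.isnan(sst) | np.isnan(mmm), np.nan, out)


def _to_day_numbers(times) -> np.ndarray:
    """Times as float days (datetime64 of any unit, or already numeric)."""
    arr = np.asarray(times)
    if np.issubdtype(arr.dtype, np.datetime64):
        return arr.astype("datetime64[s]").astype(float) / 86400.0
    return arr.astype(float)


@dataclass
class DHWSeries:
    """DHW time series for one cell, with per-time quality flags."""

    times: np.ndarray          # as passed in (datetime64 or day numbers)
    dhw: np.ndarray            # degC-weeks, >= 0
    gap_affected: np.ndarray   # True where the trailing window had missing SST
    partial: np.ndarray        # True where the window extends before the series start
    cell_id: Optional[int] = None

    def annual_max(self, year: int) -> Optional[float]:
        return annual_max_dhw(self, year)


def dhw_series(
    times,
    sst,
    mmm: float,
    window_days: float = DHW_WINDOW_DAYS,
    threshold: float = DHW_THRESHOLD_C,
    cell_id: Optional[int] = None,
) -> DHWSeries:
    """Degree Heating Weeks at every observation time of one cell.

    ``times`` must be strictly increasing (datetime64 or float days); the
    weight of each observation is the time elapsed since the previous one
    (first observation: the median spacing), so daily data weight 1 day and
    twice-weekly data 3.5 days.  Missing SST (NaN) contributes zero and
    flags every output inside its window as gap-affected.  Outputs within
    ``window_days`` of the series start are flagged ``partial``.
    """
    t = _to_day_numbers(times)
    sst = np.asarray(sst, dtype=float)
    if t.ndim != 1 or t.size != sst.size:
        raise ValueError("times and sst must be 1-D and equal length")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if t.size == 0:
        z = np.zeros(0)
        return DHWSeries(np.asarray(times), z, z.astype(bool), z.astype(bool), cell_id)
    spacing = np.diff(t)
    med = np.median(spacing) if spacing.size else 1.0
    weights = np.concatenate([[med], spacing])

    hs = hotspot(sst, mmm)
    missing = np.isnan(hs)
    contrib = np.where(~missing & (hs >= threshold), np.nan_to_num(hs) / 7.0 * weights, 0.0)

    # trailing-window sums via cumulative sums and a searchsorted window start:
    # window (t_i - window_days, t_i] inclusive of the right endpoint
    csum = np.concatenate([[0.0], np.cumsum(contrib)])
    cmiss = np.concatenate([[0], np.cumsum(missing.astype(int))])
    start = np.searchsorted(t, t - window_days, side="right")
    idx = np.arange(t.size) + 1
    dhw = csum[idx] - csum[start]
    gaps = (cmiss[idx] - cmiss[start]) > 0
    partial = (t - window_days) < t[0]
    return DHWSeries(np.asarray(times), dhw, gaps, partial, cell_id)


def annual_max_dhw(series: DHWSeries, year: int) -> Optional[float]:
    """Maximum DHW over the calendar year, or None when the year is empty."""
    years = _times_to_years(series.times)
    sel = series.dhw[years == year]
    if sel.size == 0:
        return None
    return float(sel.max())


def _times_to_years(times) -> np.ndarray:
    arr = np.asarray(times)
    if np.issubdtype(arr.dtype, np.datetime64):
        return arr.astype("datetime64[Y]").astype(int) + 1970
    raise ValueError("annual maxima need datetime64 times (calendar years)")


def annual_max_table(series_list: list[DHWSeries], years: list[int]) -> pd.DataFrame:
    """Annual maximum DHW per (cell, year): DataFrame indexed by cell_id."""
    rows = {}
    for s in series_list:
        ys = _times_to_years(s.times)
        rows[s.cell_id] = {y: (float(s.dhw[ys == y].max()) if np.any(ys == y) else np.nan) for y in years}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cell_id"
    out.columns.name = "year"
    return out.sort_index()


def stressed_mask(annual_max: pd.Series) -> pd.Series:
    """True for cells whose annual maximum DHW exceeds 0 degC-weeks.

    The complement of this mask (annual max exactly zero) is the
    pseudo-absence candidate set of the occurrence model.
    """
    return annual_max > 0.0


def dhw_matrix(
    times,
    sst: np.ndarray,
    mmm: np.ndarray,
    window_days: float = DHW_WINDOW_DAYS,
    threshold: float = DHW_THRESHOLD_C,
) -> np.ndarray:
    """Vectorised DHW for many cells sharing one time axis.

    ``sst`` is (n_cells, n_times); ``mmm`` is (n_cells,).  Equivalent to
    calling :func:`dhw_series` per row (no missing data handling; NaN SST
    is treated as no observation/zero contribution).
    """
    t = _to_day_numbers(times)
    sst = np.asarray(sst, dtype=float)
    spacing = np.diff(t)
    med = np.median(spacing) if spacing.size else 1.0
    weights = np.concatenate([[med], spacing])
    hs = np.maximum(sst - np.asarray(mmm, dtype=float)[:, None], 0.0)
    hs = np.nan_to_num(hs)
    contrib = np.where(hs >= threshold, hs / 7.0 * weights[None, :], 0.0)
    csum = np.concatenate([np.zeros((sst.shape[0], 1)), np.cumsum(contrib, axis=1)], axis=1)
    start = np.searchsorted(t, t - window_days, side="right")
    idx = np.arange(t.size) + 1
    return csum[:, idx] - csum[:, start]


def annual_max_matrix(times, dhw: np.ndarray, years: list[int]) -> pd.DataFrame:
    """Annual maxima from a (n_cells, n_times) DHW matrix; columns are years."""
    ys = _times_to_years(times)
    data = {}
    for y in years:
        sel = dhw[:, ys == y]
        data[y] = sel.max(axis=1) if sel.shape[1] else np.full(dhw.shape[0], np.nan)
    return pd.DataFrame(data)
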