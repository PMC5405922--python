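"""Ordinary indicator kriging of annual bleaching probability.

The estimator is ordinary kriging of the 0/1 bleaching indicator: for a
target location x0 and the k nearest data points, solve

    [Gamma  1] [lambda]   [gamma0]
    [1^T    0] [mu    ] = [1     ]

with Gamma_ij = gamma_model(d(x_i, x_j)) and gamma0_i = gamma_model(d(x_i, x0)),
then predict p(x0) = sum_i lambda_i z_i, clamped to [0, 1].  The constraint
row forces the weights to sum to one (unknown constant mean).  Distances are
great-circle km.

The model/results surface follows the statsmodels convention:
``IndicatorKriging(...)`` holds the data and options, ``.fit()`` estimates
the empirical semi-variogram and selects the best family by RMSE, and the
returned ``IndicatorKrigingResults`` carries the fitted structure, a
``summary()`` table, and ``predict``/``predict_cells`` methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geostat import (
    VARIOGRAM_FAMILIES,
    EmpiricalVariogram,
    ModelSelection,
    VariogramModel,
    empirical_variogram,
    haversine,
    select_model,
)
from .grid import ReefGrid, RegionSpec


class KrigingError(RuntimeError):
    """Typed failure of the kriging solve (singular system after dedup)."""


def _unit_sphere(lat, lon):
    """3-D unit-sphere embedding; chord length is monotone in great-circle distance."""
    la, lo = np.radians(np.asarray(lat, float)), np.radians(np.asarray(lon, float))
    return np.column_stack([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])


def _dedupe(lats, lons, values):
    """Merge coincident points (identical rounded coordinates) by mean value."""
    key = np.round(lats, 9) + 1j * np.round(lons, 9)
    uniq, inv = np.unique(key, return_inverse=True)
    vals = np.bincount(inv, weights=values) / np.bincount(inv)
    la = np.bincount(inv, weights=lats) / np.bincount(inv)
    lo = np.bincount(inv, weights=lons) / np.bincount(inv)
    return la, lo, vals


def solve_ordinary_kriging(
    gamma_mat: np.ndarray, gamma_vec: np.ndarray, lstsq: bool = False
) -> tuple[np.ndarray, float]:
    """Solve the ordinary-kriging system; returns (weights, Lagrange multiplier).

    With ``lstsq=True`` a minimum-norm least-squares solution is used, which
    resolves genuinely rank-deficient systems (e.g. a degenerate variogram
    with zero sill, where any weights summing to one are optimal) to the
    most uniform weight vector.
    """
    k = gamma_mat.shape[0]
    lhs = np.empty((k + 1, k + 1))
    lhs[:k, :k] = gamma_mat
    lhs[:k, k] = 1.0
    lhs[k, :k] = 1.0
    lhs[k, k] = 0.0
    rhs = np.append(gamma_vec, 1.0)
    if lstsq:
        sol = np.linalg.lstsq(lhs, rhs, rcond=1e-8)[0]
    else:
        sol = np.linalg.solve(lhs, rhs)
    return sol[:k], float(sol[k])


def krige_cell(
    target_lat: float,
    target_lon: float,
    lats,
    lons,
    values,
    model: VariogramModel,
    neighborhood: int = 64,
    clamp: bool = True,
) -> float:
    """Ordinary-kriging prediction at one target from the k nearest data points.

    Duplicate (coincident) points that make the system singular under a zero
    nugget are merged by mean value and the solve retried; a second failure
    raises :class:`KrigingError`.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    values = np.asarray(values, dtype=float)
    if lats.size == 0:
        raise ValueError("krige_cell requires at least one data point")
    if lats.size > neighborhood:
        d = haversine(target_lat, target_lon, lats, lons)
        idx = np.argpartition(d, neighborhood - 1)[:neighborhood]
        lats, lons, values = lats[idx], lons[idx], values[idx]
    # Fallback ladder for singular / near-singular systems: plain solve;
    # merge coincident points; escalating numerical nugget on the diagonal
    # (keeps the unbiasedness constraint exact; the gaussian family with a
    # near-zero fitted nugget genuinely needs this); finally a
    # truncated-SVD least-squares solve (handles exactly rank-deficient
    # pure-nugget models, where it returns the local-mean weights).
    for attempt in ("solve", "dedupe", 1e-6, 1e-4, 1e-2, "lstsq"):
        if attempt == "dedupe":
            lats, lons, values = _dedupe(lats, lons, values)
        d_mat = haversine(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
        gamma_mat = model.gamma(d_mat)
        np.fill_diagonal(gamma_mat, model.nugget)
        if isinstance(attempt, float):
            gamma_mat = gamma_mat + attempt * max(model.sill, 1e-12) * np.eye(len(lats))
        gamma_vec = model.gamma(haversine(target_lat, target_lon, lats, lons))
        try:
            w, _ = solve_ordinary_kriging(gamma_mat, gamma_vec, lstsq=(attempt == "lstsq"))
            if attempt == "lstsq" and 0 < abs(w.sum() - 1.0) < 1e-2:
                w = w / w.sum()  # truncated-SVD solution: renormalise small drift
            if not np.all(np.isfinite(w)) or abs(w.sum() - 1.0) > 1e-6:
                raise np.linalg.LinAlgError("invalid weights")
            if np.abs(w).sum() > 1e3:
                # near-singular system amplifying noise: do not clamp a wild
                # prediction, escalate to the regularised solves instead
                raise np.linalg.LinAlgError("unstable weights")
            pred = float(w @ values)
            return float(np.clip(pred, 0.0, 1.0)) if clamp else pred
        except np.linalg.LinAlgError:
            continue
    raise KrigingError("singular kriging system after deduplication and regularisation")


class IndicatorKriging:
    """Ordinary indicator-kriging model for one region-year of indicator points.

    Parameters
    ----------
    points : DataFrame with columns ``lat, lon, indicator`` (0/1); a
        ``cell_id`` column is carried through if present.
    families : candidate semi-variogram families, fitted and ranked by RMSE.
    n_bins, max_lag : empirical-variogram binning (default 15 bins to half
        the maximum pairwise distance).
    neighborhood : number of nearest data points in each local system.
    variogram_max_points : cap on points entering the empirical variogram
        (seeded subsample) to keep the pair computation quadratic-in-small.
    """

    def __init__(
        self,
        points: pd.DataFrame,
        families: Sequence[str] = VARIOGRAM_FAMILIES,
        n_bins: int = 15,
        max_lag: Optional[float] = None,
        neighborhood: int = 64,
        weighting: str = "ols",
        variogram_max_points: int = 3000,
        random_state: int = 0,
    ):
        required = {"lat", "lon", "indicator"}
        if not required.issubset(points.columns):
            raise ValueError(f"points must have columns {sorted(required)}")
        self.points = points.reset_index(drop=True)
        self.families = tuple(families)
        self.n_bins = n_bins
        self.max_lag = max_lag
        self.neighborhood = neighborhood
        self.weighting = weighting
        self.variogram_max_points = variogram_max_points
        self.random_state = random_state

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "IndicatorKriging":
        return cls(df, **kwargs)

    def fit(self) -> "IndicatorKrigingResults":
        pts = self.points
        if len(pts) > self.variogram_max_points:
            rng = np.random.default_rng(self.random_state)
            sub = pts.iloc[np.sort(rng.choice(len(pts), self.variogram_max_points, replace=False))]
        else:
            sub = pts
        empirical = None
        selection = ModelSelection(fits=[], model=None)
        if len(sub) >= 2 and sub["indicator"].nunique() >= 1:
            try:
                empirical = empirical_variogram(
                    sub["lat"].to_numpy(), sub["lon"].to_numpy(), sub["indicator"].to_numpy(float),
                    n_bins=self.n_bins, max_lag=self.max_lag,
                )
                selection = select_model(empirical, self.families, weighting=self.weighting)
            except ValueError:
                pass
        return IndicatorKrigingResults(model=self, empirical=empirical, selection=selection)


@dataclass
class IndicatorKrigingResults:
    """Fitted indicator-kriging structure for one set of indicator points."""

    model: IndicatorKriging
    empirical: Optional[EmpiricalVariogram]
    selection: ModelSelection
    clamped_fraction: float = field(default=0.0, init=False)

    @property
    def converged(self) -> bool:
        return self.selection.model is not None

    @property
    def variogram(self) -> Optional[VariogramModel]:
        return self.selection.model

    def predict(self, lats, lons) -> np.ndarray:
        """Kriged bleaching probability at arbitrary locations (clamped to [0,1]).

        Requires a converged variogram; callers wanting the zero-probability
        fallback for non-converged region-years should use
        :func:`krige_region`, which encodes that rule.
        """
        if not self.converged:
            raise KrigingError("no converged variogram model; cannot predict")
        vg = self.selection.model
        pts = self.model.points
        dlat = pts["lat"].to_numpy(float)
        dlon = pts["lon"].to_numpy(float)
        dval = pts["indicator"].to_numpy(float)
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        k = min(self.model.neighborhood, dlat.size)
        tree = cKDTree(_unit_sphere(dlat, dlon))
        _, nbr = tree.query(_unit_sphere(lats, lons), k=k)
        nbr = np.asarray(nbr).reshape(lats.size, k)
        out = np.empty(lats.size)
        n_clamped = 0
        for i in range(lats.size):
            idx = nbr[i]
            raw = krige_cell(
                lats[i], lons[i], dlat[idx], dlon[idx], dval[idx], vg,
                neighborhood=k, clamp=False,
            )
            if raw < 0.0 or raw > 1.0:
                n_clamped += 1
            out[i] = np.clip(raw, 0.0, 1.0)
        self.clamped_fraction = n_clamped / max(lats.size, 1)
        return out

    def summary(self) -> str:
        lines = ["Ordinary indicator kriging", "=" * 60]
        lines.append(f"n points:           {len(self.model.points)}")
        lines.append(f"n presence (z=1):   {int((self.model.points['indicator'] == 1).sum())}")
        lines.append(f"neighborhood:       {self.model.neighborhood}")
        if self.empirical is not None:
            lines.append(f"variogram bins:     {len(self.empirical.lag_centres)} to {self.empirical.max_lag:.1f} km")
        if self.converged:
            vg = self.selection.model
            shape = f" shape={vg.shape:.3g}" if vg.shape is not None else ""
            lines.append(
                f"selected model:     {vg.family} (nugget={vg.nugget:.4g}, "
                f"psill={vg.partial_sill:.4g}, range={vg.range_km:.4g} km{shape}, rmse={vg.rmse:.3e})"
            )
        else:
            lines.append("selected model:     none (all families failed -> zero-probability fallback)")
        lines.append("-" * 60)
        for f in self.selection.fits:
            if isinstance(f, VariogramModel):
                lines.append(f"  {f.family:<14s} rmse={f.rmse:.4e}")
            else:
                lines.append(f"  {f.family:<14s} FAILED ({f.reason})")
        return "\n".join(lines)


def krige_region(
    region: RegionSpec,
    year: int,
    points: pd.DataFrame,
    grid: ReefGrid,
    families: Sequence[str] = VARIOGRAM_FAMILIES,
    **options,
) -> pd.DataFrame:
    """Kriged probability fragment for every reef cell of one region-year.

    If the region-year has no presence points, or every semi-variogram
    family fails to converge, every cell receives probability zero with
    ``zero-fallback`` provenance (so a year without usable reports
    contributes zero bleaching area even where bleaching was observed).
    Returns columns ``cell_id, lat, lon, year, probability, provenance``.
    """
    cells = grid.region_cells(region)
    frag = pd.DataFrame(
        {
            "cell_id": cells.index.to_numpy(),
            "lat": cells["lat"].to_numpy(),
            "lon": cells["lon"].to_numpy(),
            "year": year,
            "probability": 0.0,
            "provenance": "zero-fallback",
        }
    )
    if len(cells) == 0:
        return frag
    in_region = points.loc[region.contains(points["lat"].to_numpy(), points["lon"].to_numpy())]
    n_presence = int((in_region["indicator"] == 1).sum()) if len(in_region) else 0
    if n_presence == 0:
        return frag
    res = IndicatorKriging(in_region, families=families, **options).fit()
    if not res.converged:
        return frag
    frag["probability"] = res.predict(frag["lat"].to_numpy(), frag["lon"].to_numpy())
    frag["provenance"] = "kriged"
    return frag


def merge_overlaps(fragments: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-region fragments into one probability grid.

    Cells appearing in a single fragment keep their value; cells covered by
    two or more fragments (the deliberately overlapping Pacific sections)
    get the arithmetic mean of the fragment values, with provenance
    ``averaged-overlap``.
    """
    if not fragments:
        return pd.DataFrame(columns=["cell_id", "lat", "lon", "year", "probability", "provenance"])
    allf = pd.concat(fragments, ignore_index=True)
    grp = allf.groupby("cell_id", sort=True)
    out = grp.agg(
        lat=("lat", "first"),
        lon=("lon", "first"),
        year=("year", "first"),
        probability=("probability", "mean"),
        n=("probability", "size"),
        kriged=("provenance", lambda s: (s == "kriged").any()),
        provenance=("provenance", "first"),
    ).reset_index()
    # overlap provenance only matters where something was actually kriged;
    # two zero-fallback fragments averaged are still a zero fallback
    out.loc[(out["n"] > 1) & out["kriged"], "provenance"] = "averaged-overlap"
    out.loc[out["kriged"] & (out["n"] == 1), "provenance"] = "kriged"
    out.loc[~out["kriged"], "provenance"] = "zero-fallback"
    return out.drop(columns=["n", "kriged"])
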