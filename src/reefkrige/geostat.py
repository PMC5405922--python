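"""Empirical indicator semi-variograms and model fitting/selection.

The semi-variogram gamma(h) is half the expected squared difference between
indicator values separated by distance h.  Nine parametric families are
supported (exponential, spherical, gaussian, matern, stein_matern, circular,
linear, bessel, pentaspherical), following the parameterisations used by the
R ``gstat`` package.  Each candidate family is fitted to the binned
empirical semi-variogram by least squares and the family with the lowest
root-mean-squared error against the empirical bins is selected.

All distances are great-circle kilometres (haversine, R = 6371 km): domain
splits are defined in kilometres, so one metric is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import optimize, special

EARTH_RADIUS_KM = 6371.0

#: Family names in canonical order (also the tie-break order of select_model).
VARIOGRAM_FAMILIES = (
    "exponential",
    "spherical",
    "gaussian",
    "matern",
    "stein_matern",
    "circular",
    "linear",
    "bessel",
    "pentaspherical",
)

#: Families whose semi-variance approaches nugget + partial_sill at large h.
BOUNDED_FAMILIES = frozenset(f for f in VARIOGRAM_FAMILIES if f != "linear")


def haversine(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on a sphere of radius 6371 km (vectorised)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Model families: correlation-like "structure" functions g(h) in [0, 1]
# with g(0)=0 and (bounded families) g(h) -> 1; gamma = nugget + psill * g.


def _g_exponential(h, a, kappa):
    return 1.0 - np.exp(-h / a)


def _g_spherical(h, a, kappa):
    r = np.minimum(h / a, 1.0)
    return 1.5 * r - 0.5 * r**3


def _g_gaussian(h, a, kappa):
    return 1.0 - np.exp(-((h / a) ** 2))


def _matern_corr(x, kappa):
    # 2^(1-k)/Gamma(k) * x^k * K_k(x), continuous at 0 with value 1
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    pos = x > 0
    xp = x[pos]
    with np.errstate(over="ignore", invalid="ignore"):
        val = (2.0 ** (1.0 - kappa) / special.gamma(kappa)) * xp**kappa * special.kv(kappa, xp)
    out[pos] = np.where(np.isfinite(val), val, 0.0)  # kv underflow at large x -> corr 0
    return np.clip(out, 0.0, 1.0)


def _g_matern(h, a, kappa):
    return 1.0 - _matern_corr(h / a, kappa)


def _g_stein_matern(h, a, kappa):
    # Stein's parameterisation: argument scaled by 2*sqrt(kappa) so the
    # practical range is nearly invariant to the smoothness parameter.
    return 1.0 - _matern_corr(2.0 * np.sqrt(kappa) * h / a, kappa)


def _g_circular(h, a, kappa):
    r = np.minimum(h / a, 1.0)
    return (2.0 / np.pi) * (r * np.sqrt(np.clip(1.0 - r**2, 0.0, 1.0)) + np.arcsin(r))


def _g_linear(h, a, kappa):
    # Unbounded: gamma grows linearly; partial_sill / range_km is the slope.
    return h / a


def _g_bessel(h, a, kappa):
    # K1-Bessel family: correlation (h/a) K_1(h/a), limit 1 at h=0.
    x = np.asarray(h, dtype=float) / a
    out = np.zeros_like(x)
    pos = x > 0
    with np.errstate(over="ignore", invalid="ignore"):
        val = x[pos] * special.kv(1, x[pos])
    corr = np.where(np.isfinite(val), val, 0.0)
    out[pos] = 1.0 - np.clip(corr, 0.0, 1.0)
    return out


def _g_pentaspherical(h, a, kappa):
    r = np.minimum(h / a, 1.0)
    return (15.0 / 8.0) * r - (5.0 / 4.0) * r**3 + (3.0 / 8.0) * r**5


_STRUCTURES: dict[str, Callable] = {
    "exponential": _g_exponential,
    "spherical": _g_spherical,
    "gaussian": _g_gaussian,
    "matern": _g_matern,
    "stein_matern": _g_stein_matern,
    "circular": _g_circular,
    "linear": _g_linear,
    "bessel": _g_bessel,
    "pentaspherical": _g_pentaspherical,
}

#: Families carrying a smoothness parameter kappa.
SHAPE_FAMILIES = frozenset({"matern", "stein_matern"})


@dataclass(frozen=True)
class VariogramModel:
    """A fitted (or specified) semi-variogram model.

    gamma(0) = nugget by convention here: the nugget enters the kriging
    matrix diagonal, so a nonzero nugget yields a smoothing (inexact)
    interpolator, which is what keeps co-located presence/pseudo-absence
    points from forcing probability 1.
    """

    family: str
    nugget: float
    partial_sill: float
    range_km: float
    shape: Optional[float] = None
    rmse: float = float("nan")

    def __post_init__(self):
        if self.family not in _STRUCTURES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_km <= 0:
            raise ValueError("require nugget >= 0, partial_sill >= 0, range_km > 0")

    def gamma(self, h):
        h = np.asarray(h, dtype=float)
        kappa = self.shape if self.shape is not None else 0.5
        g = _STRUCTURES[self.family](h, self.range_km, kappa)
        return self.nugget + self.partial_sill * g

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


def model_gamma(model: VariogramModel, h):
    """Evaluate a model semi-variogram at distance(s) h (km)."""
    return model.gamma(h)


@dataclass(frozen=True)
class FitFailure:
    """Typed fit failure (insufficient data or non-convergence)."""

    family: str
    reason: str

    @property
    def converged(self) -> bool:
        return False


@dataclass
class EmpiricalVariogram:
    """Binned empirical semi-variogram.

    ``gamma`` is NaN for bins with no pairs; ``pair_counts`` always sums to
    the number of pairs at or below ``max_lag``.
    """

    lag_centres: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray
    max_lag: float

    @property
    def usable(self) -> np.ndarray:
        return np.isfinite(self.gamma)


def pairwise_haversine(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Full n x n great-circle distance matrix in km."""
    return haversine(lats[:, None], lons[:, None], lats[None, :], lons[None, :])


def empirical_variogram(
    lats,
    lons,
    values,
    n_bins: int = 15,
    max_lag: Optional[float] = None,
) -> EmpiricalVariogram:
    """Method-of-moments semi-variogram of scattered (indicator) data.

    gamma(bin) = sum over pairs in bin of (z_i - z_j)^2 / (2 N).  Default
    ``max_lag`` is half the maximum pairwise distance.  Raises ValueError
    for fewer than two points.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    values = np.asarray(values, dtype=float)
    n = lats.size
    if n < 2:
        raise ValueError("empirical variogram requires at least 2 points")
    d = pairwise_haversine(lats, lons)
    iu, ju = np.triu_indices(n, k=1)
    dist = d[iu, ju]
    sq = (values[iu] - values[ju]) ** 2
    if max_lag is None:
        max_lag = float(dist.max()) / 2.0
    if max_lag <= 0:
        raise ValueError("max_lag must be positive (all points coincident?)")
    width = max_lag / n_bins
    keep = dist <= max_lag
    idx = np.minimum((dist[keep] / width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=sq[keep], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * counts), np.nan)
    centres = (np.arange(n_bins) + 0.5) * width
    return EmpiricalVariogram(centres, gamma, counts, float(max_lag))


def _initial_guesses(emp: EmpiricalVariogram) -> tuple[float, float, float]:
    h = emp.lag_centres[emp.usable]
    g = emp.gamma[emp.usable]
    nugget0 = max(float(g[0]), 0.0)
    sill0 = float(np.mean(g[-max(1, len(g) // 3):]))
    psill0 = max(sill0 - nugget0, 1e-6 + 0.1 * abs(sill0))
    range0 = float(h[-1]) / 2.0
    return nugget0, psill0, range0


def fit_model(
    emp: EmpiricalVariogram,
    family: str,
    init: Optional[Sequence[float]] = None,
    weighting: str = "ols",
) -> Union[VariogramModel, FitFailure]:
    """Least-squares fit of one family to the binned empirical semi-variogram.

    ``weighting='ols'`` (default) is plain least squares on binned gammas;
    ``'cressie'`` weights residuals by N(h)/h^2.  The reported ``rmse`` is
    always the unweighted sqrt(mean((gamma_model - gamma_emp)^2)) over
    usable bins, which is the model-selection criterion.  Returns a typed
    ``FitFailure`` instead of raising on non-convergence.
    """
    if family not in _STRUCTURES:
        raise ValueError(f"unknown variogram family {family!r}")
    use = emp.usable
    h = emp.lag_centres[use]
    g = emp.gamma[use]
    if h.size < 3:
        return FitFailure(family, "insufficient-data: fewer than 3 usable bins")
    if weighting == "ols":
        w = np.ones_like(h)
    elif weighting == "cressie":
        w = emp.pair_counts[use] / np.maximum(h, 1e-9) ** 2
        w = w / w.mean()
    else:
        raise ValueError("weighting must be 'ols' or 'cressie'")
    sw = np.sqrt(w)
    has_shape = family in SHAPE_FAMILIES
    struct = _STRUCTURES[family]

    def resid(theta):
        n, s, a = theta[0], theta[1], theta[2]
        kappa = theta[3] if has_shape else 0.5
        return sw * (n + s * struct(h, a, kappa) - g)

    n0, s0, a0 = _initial_guesses(emp) if init is None else (init[0], init[1], init[2])
    hmax = float(h[-1])
    gmax = float(np.max(g)) if np.max(g) > 0 else 1.0
    # keep parameters on the scale of the data: an indicator semi-variogram
    # is bounded by 0.5, so sills far above the empirical gammas and ranges
    # far beyond the observed lags are extrapolation artifacts, not fits
    lo = [0.0, 0.0, 1e-6 * hmax]
    hi = [2.0 * gmax, 5.0 * gmax, 10.0 * hmax]
    starts = [(n0, s0, a0), (0.0, n0 + s0, hmax / 3.0), (n0, s0, hmax)]
    if has_shape:
        lo.append(0.05)
        hi.append(10.0)
        starts = [st + (k,) for st in starts for k in (0.5, 1.5)]
        if init is not None and len(init) > 3:
            starts.insert(0, tuple(init))
    best = None
    for st in starts:
        x0 = np.clip(np.asarray(st, dtype=float), lo, hi)
        try:
            with np.errstate(all="ignore"):
                sol = optimize.least_squares(resid, x0, bounds=(lo, hi), max_nfev=2000)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitFailure(family, "convergence failure: optimizer did not produce finite parameters")
    n, s, a = best.x[0], best.x[1], best.x[2]
    kappa = float(best.x[3]) if has_shape else None
    # snap a negligible partial sill to exactly zero: a pure-nugget model is
    # then solved as the (rank-deficient) local-mean limit instead of an
    # ill-conditioned near-singular kriging system
    if s < 1e-6 * max(n + s, 1e-12):
        s = 0.0
    model = VariogramModel(family, float(n), float(s), float(max(a, 1e-12)), shape=kappa)
    rmse = float(np.sqrt(np.mean((model.gamma(h) - g) ** 2)))
    if not np.isfinite(rmse):
        return FitFailure(family, "convergence failure: non-finite rmse")
    return replace(model, rmse=rmse)


@dataclass
class ModelSelection:
    """Outcome of fitting a list of families and choosing the lowest RMSE."""

    fits: list  # VariogramModel or FitFailure, in input family order
    model: Optional[VariogramModel]

    @property
    def all_failed(self) -> bool:
        return self.model is None

    def to_frame(self):
        import pandas as pd

        rows = []
        for f in self.fits:
            if isinstance(f, VariogramModel):
                rows.append(
                    {"family": f.family, "converged": True, "nugget": f.nugget,
                     "partial_sill": f.partial_sill, "range_km": f.range_km,
                     "shape": f.shape, "rmse": f.rmse, "reason": ""}
                )
            else:
                rows.append(
                    {"family": f.family, "converged": False, "nugget": np.nan,
                     "partial_sill": np.nan, "range_km": np.nan, "shape": np.nan,
                     "rmse": np.nan, "reason": f.reason}
                )
        return pd.DataFrame(rows)


def select_model(
    emp: EmpiricalVariogram,
    families: Sequence[str] = VARIOGRAM_FAMILIES,
    weighting: str = "ols",
) -> ModelSelection:
    """Fit every family; return the converged fit with minimal RMSE.

    Ties break by family list order.  If every family fails (too few usable
    bins, optimizer divergence) the selection carries ``model=None`` and the
    caller falls back to a zero-probability surface for that region-year.
    """
    if not families:
        raise ValueError("families must be non-empty")
    fits = [fit_model(emp, fam, weighting=weighting) for fam in families]
    best = None
    for f in fits:
        if isinstance(f, VariogramModel) and (best is None or f.rmse < best.rmse):
            best = f
    return ModelSelection(fits=fits, model=best)
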