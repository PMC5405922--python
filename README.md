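# reefkrige

Gridded probability maps of mass coral bleaching occurrence from
severity-coded field reports and satellite thermal stress.

## The problem

Historical records of mass coral bleaching are voluntary, clustered in
well-monitored places, and silent about the vast majority of reefs — so a
raw count of reports says more about observation effort than about how much
bleaching happened. `reefkrige` implements the geostatistical approach to
this problem: rasterise the reports onto a 0.04° × 0.04° reef grid, add
"pseudo-absences" wherever satellite data show a year with no thermal
stress at all, and interpolate with **ordinary indicator kriging** to an
annual map of the probability that moderate-to-severe bleaching occurred in
every reef cell. Downstream statistics (reef area above probability
thresholds, thermal-stress levels of probably-bleached reefs, changes
between the pre- and post-1998 eras) are then area-based and comparable
across years, not report-count based.

It is written for spatial ecologists and climate-impact researchers who
have (a) bleaching report tables in the ReefBase-style schema, (b) SST
series plus a maximum-monthly-mean (MMM) climatology per grid cell, and
(c) a rasterised reef-area mask — or who want to study the method itself
on fully synthetic data with known ground truth.

## The method

**Severity coding.** Percent bleached maps to an ordinal code: −1 unknown,
0 none, 1 mild (1–10%), 2 moderate (11–50%), 3 severe (>50%). Only codes 2
and 3 count as bleaching presence; milder or unknown reports are too often
misread non-lethal paling.

**Thermal stress.** HotSpot(t) = max(0, SST(t) − MMM), and Degree Heating
Weeks accumulate HotSpots of at least 1 °C over a trailing 84-day window:

    DHW(t) = Σ_{s ∈ (t−84d, t]} HotSpot(s)/7 · days(s),   HotSpot(s) ≥ 1 °C

in °C-weeks. A reef cell with annual maximum DHW = 0 experienced no
thermal stress that year and becomes an indicator-0 *pseudo-absence*; a
cell with ≥1 severity-2/3 report is an indicator-1 *presence* (a cell can
be both).

**Indicator kriging.** Per region and year, the empirical semi-variogram
γ̂(h) = Σ(z_i − z_j)²/2N(h) of the indicator points is fitted by least
squares with nine model families (exponential, spherical, gaussian,
Matérn, Stein's Matérn, circular, linear, Bessel, pentaspherical); the
family with the lowest RMSE against the binned gammas wins. The
probability at each reef cell x₀ solves the ordinary-kriging system over
the k = 64 nearest indicator points,

    [Γ 1; 1ᵀ 0] [λ; μ] = [γ₀; 1],   p(x₀) = Σ λ_i z_i ∈ [0, 1],

with Γ_ij = γ(d_ij) (haversine km). Regions are the Caribbean, Indian
Ocean, Eastern Pacific, and the main Pacific in three sections overlapping
by ≥1000 km whose predictions are averaged in the overlaps. A region-year
with no presence points, or where every variogram family fails to
converge, falls back to probability zero everywhere.

## Worked example

Fit the kriging model to 145 indicator points (a presence cluster near
0° N 100° E inside a field of absences) and predict along a transect:

```python
import numpy as np, pandas as pd
from reefkrige.krige import IndicatorKriging

rng = np.random.default_rng(21)
pts = pd.DataFrame({
    "lat": np.concatenate([rng.normal(0.0, 0.5, 25), rng.uniform(-6, 6, 120)]),
    "lon": np.concatenate([rng.normal(100.0, 0.5, 25), rng.uniform(94, 112, 120)]),
    "indicator": np.concatenate([np.ones(25), np.zeros(120)]).astype(int),
})
res = IndicatorKriging(pts, random_state=0).fit()
print(res.summary())
print(res.predict([0.0, 0.0, 0.0, 0.0], [100.0, 101.0, 104.0, 110.0]))
```

```
Ordinary indicator kriging
============================================================
n points:           145
n presence (z=1):   25
neighborhood:       64
variogram bins:     15 to 1106.2 km
selected model:     circular (nugget=0.02129, psill=0.1448, range=216.6 km, rmse=3.375e-02)
------------------------------------------------------------
  exponential    rmse=3.4993e-02
  spherical      rmse=3.3796e-02
  ...
[1.    0.383 0.038 0.   ]
```

The selected circular model decorrelates at ~217 km, and the predicted
bleaching probability falls from 1.0 inside the cluster to the background
0 beyond the variogram range.

The full pipeline runs end to end on synthetic data (or on file inputs —
see the `reefkrige run --help` CLI):

```python
import reefkrige as rk

res = rk.run_pipeline(rk.PipelineConfig(synth=rk.SynthConfig(), seed=1))
print(res.areas.table.loc[[1987, 1998, 2005]].round(1))
print(res.areas.fold_changes())
```

```
      more_likely_than_not  likely  very_likely
year
1987                 196.8   174.5        148.7
1998                2430.2  2420.9       2386.0
2005                1152.1  1138.5       1119.5
{'more_likely_than_not': 6.53, 'likely': 7.77, 'very_likely': 8.03}
```

The table gives reef area (km²) whose bleaching probability exceeds 0.50
("more likely than not"), 0.66 ("likely") and 0.90 ("very likely") per
year; the fold changes compare the mean annual area between 1999–2010 and
1985–1996. The synthetic world plants events whose late-period extent is
eight times the early period, and the recovered fold changes bracket that
truth.

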