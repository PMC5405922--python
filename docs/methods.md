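# Methods

This note documents the model, its parameters and numerical choices, what
the synthetic generator does and does not emulate, and the design
decisions taken where the method left room.

## The occurrence model

The quantity being estimated is, per calendar year and per 0.04° × 0.04°
reef cell, the probability that moderate-to-severe bleaching (severity
code 2 or 3, i.e. >10% of coral bleached) occurred. The estimator is
ordinary indicator kriging: the observed data are 0/1 indicator points,
and the kriged value at an unsampled cell is a weighted average of nearby
indicators with weights from the fitted spatial-correlation structure,
interpretable as a probability after clamping to [0, 1].

Two data sources feed the indicators:

* **Presences** — a cell with at least one in-year report of severity 2
  or 3. Mild (1) and unknown (−1) reports are excluded: in voluntary
  monitoring they frequently record non-lethal paling or misreadings, and
  treating them as events would contaminate the probability maps.
* **Pseudo-absences** — a reef cell whose annual maximum Degree Heating
  Week value is exactly 0 °C-weeks. No thermal stress all year is taken
  as evidence that no warm-water mass bleaching occurred, standing in for
  the "no bleaching" surveys that voluntary databases rarely file.
  Thermal stress enters the model *only* through this rule; DHW magnitude
  is never a covariate, so the maps reflect the observations, the reef
  geography and the absence of stress, nothing else.

A cell can carry both a presence and a pseudo-absence in the same year
(observed bleached, yet no in-year stress). Its kriged probability is then
strictly below 1, which is the intended behaviour of the model rather
than an inconsistency: the two points encode conflicting evidence.

### Severity coding

Percent bleached maps to the ordinal code with right-closed bands:
missing → −1, 0 → 0, (0, 10] → 1, (10, 50] → 2, (50, 100] → 3. The
right-closed convention makes the printed labels "1–10%", "11–50%",
">50%" exclusive and exhaustive for integer percents; fractional values
between bands (10.5) fall upward. Stored codes that contradict the stored
percent are rejected at ingest with a machine-readable reason rather than
silently recoded.

### Degree Heating Weeks

DHW follows the NOAA Coral Reef Watch convention: positive SST anomalies
relative to the maximum monthly mean (MMM) climatology — HotSpots — of at
least 1 °C are accumulated over a trailing 84-day (12-week) window and
divided by 7 to give °C-weeks. Both the window length (`window_days`,
default 84) and the accumulation threshold (`threshold`, default 1 °C)
are parameters, since different reconstructions of the metric have used
slight variants. Observations are weighted by the days they represent
(1 for daily series, 3.5 for twice-weekly satellite composites), inferred
from the time spacing. Missing SST contributes zero and flags every
output in its window as gap-affected; outputs whose window precedes the
series start are flagged partial. The annual maximum is used because
report dates are too unreliable to align stress with bleaching onset —
which also means the per-class DHW statistics overestimate the stress at
which bleaching began.

### Variogram estimation and selection

Per region-year, the empirical semi-variogram of the indicator points is
computed by the method of moments in 15 equal-width bins out to half the
maximum pairwise distance (both configurable). Distances are great-circle
kilometres (haversine, R = 6371 km) everywhere — the domain splits are
specified in km, and mixing degree-based and km-based metrics invites
subtle bugs.

Nine model families are fitted: exponential, spherical, gaussian, Matérn
(smoothness κ fitted in [0.05, 10]), Stein's Matérn (argument scaled by
2√κ so the practical range is nearly κ-invariant), circular, linear,
Bessel (the K₁-Bessel family, with correlation (h/a)K₁(h/a)), and
pentaspherical. Formulas follow the conventions of the R `gstat` package,
which is where this set of family names comes from. The source analysis
this design follows announced "eight" modelled semi-variograms but listed
these nine family names; rather than guess which to drop, all nine are
fitted.

Fitting is least squares on the binned gammas (Cressie N(h)/h² weighting
available via `weighting="cressie"`), multi-started over a few range and
smoothness initials. Parameters are bounded to the scale of the data:
nugget ≤ 2×, partial sill ≤ 5× the largest empirical gamma, range ≤ 10×
the largest lag. An indicator semi-variogram cannot exceed 0.5, so sills
of 10² and ranges of 10⁵ km — which unconstrained optimisers happily
produce when the empirical gammas are nearly flat — are extrapolation
artifacts, not fits. A partial sill below 10⁻⁶ of the total sill is
snapped to exactly zero so the pure-nugget limit is handled as such
downstream. Non-convergence and insufficient data (<3 usable bins) are
returned as typed failures, not exceptions. The reported RMSE is always
the unweighted √mean((γ_model − γ̂)²) over usable bins, and the family
with the lowest RMSE is selected (ties break by the canonical family
order). If every family fails, the region-year falls back to zero
probability everywhere — a deliberate bias toward under- rather than
over-stating bleaching extent.

### The kriging solve

Predictions use the k = 64 nearest indicator points (configurable;
pseudo-absences can number in the tens of thousands, so a global system
is impractical), found via a k-d tree on the unit-sphere embedding, whose
chord distance is monotone in great-circle distance. The ordinary-kriging
system with a Lagrange multiplier enforces Σλ = 1. By convention here
γ(0) = nugget on the matrix diagonal, so a nonzero nugget produces a
smoothing rather than exactly interpolating estimator — with a zero
nugget, exactness at data points holds to solver precision.

Singular and near-singular systems get a fallback ladder: (1) merge
coincident points by mean value (the presence + pseudo-absence pair in
one cell under a zero nugget); (2) escalating numerical nugget (10⁻⁶,
10⁻⁴, 10⁻² of the sill) — the gaussian family with a near-zero fitted
nugget genuinely requires this, a well-known pathology; (3) truncated-SVD
least squares, which resolves exactly rank-deficient pure-nugget systems
to the local-mean weights. Solutions whose absolute weight sum exceeds
10³ are treated as noise-amplifying and escalated instead of clamped.
Final predictions are clamped to [0, 1] and the clamped fraction is
recorded.

### Regions and overlap averaging

Kriging runs separately for the Caribbean, Indian Ocean, Eastern Pacific
(isolated from other Pacific reefs), and the main Pacific in three
sections overlapping by 12° of longitude (≥1000 km equatorward of 30°).
Overlap cells take the arithmetic mean of the overlapping sections'
estimates, removing the arbitrary seam of the split.

### Downstream statistics

Reef areas above the 0.50 / 0.66 / 0.90 probability thresholds use strict
exceedance and per-cell reef areas. Probability classes for DHW
statistics use strict lower and inclusive upper bounds (">50–66%" is
(0.50, 0.66]); pooling is over all (cell, year) pairs weighted by cell
reef area, with the weighted median defined as the value where cumulative
weight first reaches half the total. Period contrasts compare 1985–1996
with 1999–2010 (the 1997/98 El Niño straddles the gap) as
mean(late)/mean(early) fold changes, tested with Welch's two-tailed
unequal-variance t-test; trends are OLS slopes of the annual reef-area-
weighted mean of annual maximum DHW on year (constant series return
slope 0, p 1 by convention).

## The synthetic generator

The generator exists so every stage — and the full pipeline — can be
validated against known ground truth. It emulates: a clustered
archipelago reef grid with per-cell areas; twice-weekly SST with a
seasonal cycle, noise capped below the DHW accumulation threshold outside
events, and planted warm events (SST = MMM + amplitude over an 84-day
window) so annual maximum DHW is positive exactly in event patches and
has the closed form amplitude × duration/7 there; a latent bleaching-
probability field (clipped Gaussian random field with a configured
variogram, raised to 0.9 inside event patches); spatially clustered
survey effort (hub-distance-decaying survey probability over a uniform
floor); and report tables with severity-coding noise, non-thermal-cause
comments and land-coordinate contaminants that exercise the QC path.

The default schedule plants two small early-period events (1987, 1995;
2% of cells each) and four larger late-period events (1999, 2002, 2005,
2010; 6–12%) whose summed extents differ by a factor of exactly eight,
plus a large 1998 event between the periods — the magnitude of change
across the 1997/98 El Niño the analysis is designed to detect. The
background probability of severe bleaching without any thermal stress is
nearly zero (0.002 plus a small spatial field): warm-water mass bleaching
without stress is misreport-level noise, and this is what leaves many
region-years with no usable reports, reproducing the sparse
year-by-region availability pattern of the real record.

What the generator does **not** emulate: real reef geography and area
distributions, ENSO teleconnections (event locations are random patches),
reporting-delay and metadata errors beyond schema-level contamination,
observer-dependent severity estimation, and any coupling between
consecutive years (latent fields are independent across years). Passing
recovery tests on this world therefore demonstrates the correctness of
the machinery — coding rules, DHW arithmetic, variogram fitting, kriging,
area statistics — not the ecological fidelity of the probability maps on
real data.

## Problem sizes and defaults

Default synthetic study: 1200 reef cells across six archipelago clusters,
26 years (1985–2010), twice-weekly SST, ~19 000 reports. This is a
deliberately desk-scale analogue of the global analysis (which has
~300 000 reef cells); the statistics that matter — fold changes, MAE
against the latent field, class contrasts — are ratios and averages that
do not require the full global cell count to be meaningful. An end-to-end
run takes well under a minute on one core.

## Known limitations

* Zero-fallback region-years bias every extent statistic downward, by
  construction; the fold changes partially cancel this but years where
  only one period's interpolation failed do not.
* Indicator kriging ignores the binomial sampling noise of single-survey
  cells; a cell's single severity-2 report is treated as certainty 1.
* The local-neighborhood solve (k = 64) introduces slight discontinuities
  at neighborhood boundaries; they are far below the probability
  resolution of interest.
* Variogram model selection by in-sample RMSE favours flexible families
  and carries no parsimony penalty; it is retained because it is the
  selection rule of the method being implemented.
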