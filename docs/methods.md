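# Methods

## The water-table model

The hydrological core is a one-dimensional monthly water balance for a
static peat column (default depth 2 m; peat growth and carbon cycling
are out of scope).  State is the water deficit `D` (mm of water missing
relative to saturation at the surface).  Each month:

```
D' = D - P + R(P, slope, WTD) + AET(T, month, topography, WTD, PFT)
```

with `D'` clamped at the ponding floor (default 5 cm of surface water,
deficit -50 mm); anything beyond the floor spills to runoff.  Mass
balance `P = ΔS + R + AET + spill` closes to machine precision every
month and is asserted in the tests at 1e-6 mm.

**Specific yield.** `s(z) = max(s_min, s0 e^{-z/z_s})` with `s0 = 0.5`,
`s_min = 0.05`, `z_s = 20 cm`: the loose acrotelm drains easily, the
dense catotelm barely at all.  Deficit and WTD are linked by
`D = 10 ∫_0^w s(z) dz` (analytic in both directions; ponded water uses a
unit storage coefficient, so 10 mm of surplus is 1 cm of ponding).  The
inversion is exact, tested against numerical quadrature.

**Runoff.** A coefficient
`c = clip(c0 + a·tan(slope), 0, 0.95) · exp(-max(WTD,0)/w0)` with
`c0 = 0.1`, `a = 1`, `w0 = 15 cm` multiplies the month's rain: steeper
cells shed more; a deep water table means an absorbent column that sheds
less.

**Evapotranspiration.** Potential ET is a temperature index:
`PET = k · T' · L(month, latitude)` with `k = 6 mm/°C/month`, zero when
`T' ≤ 0`, where `T'` corrects the grid-square temperature by an
elevation lapse of 0.6 °C / 100 m (reference elevation 400 m,
configurable) and a ±0.5 °C cosine aspect term (south-facing warmer;
flat cells take no aspect term), and `L` is the relative daylength
(annual mean 1).  At typical upland temperatures this yields an annual
PET near 450–500 mm, consistent with UK blanket-bog settings.  Actual ET
equals PET while the water table is within the root zone and decays as
`exp(-(WTD - z_root)/20 cm)` below it; the effective rooting depth
interpolates between 5 cm (wet-adapted vegetation) and 30 cm (shrubby
vegetation) by the plant-functional-type mix.

**Vegetation feedback.** The wet-adapted fraction follows a logistic in
the trailing mean WTD, `1 / (1 + exp((m - 10)/5))` (cm), with a
five-year exponential memory during simulation and a per-cycle update
during spin-up.

**Sub-stepping.** Fluxes are applied in 30 equal sub-steps per month,
re-evaluating the runoff coefficient and ET throttle at the evolving
depth.  The continuous-time balance is a cooperative dynamical system
(wetter stays wetter under more rain; warmer stays drier under more ET),
so its flow is monotone in the forcing; whole-month explicit steps can
overshoot and break those comparisons, while quasi-daily sub-steps keep
the discrete update inside the monotone regime.  The monotonicity suite
(rain x1.5 never deepens the equilibrium summer water table; +1 °C never
shallows it; steeper never shallows it) is asserted over 20 random
topographies.

**Spin-up** repeats a baseline climate, refreshing the vegetation mix
from each cycle's annual mean WTD, until the annual mean moves less than
0.1 cm between cycles (cap 200 cycles, warning on non-convergence).

These functional forms are this package's own concrete choices: they
honour the qualitative structure of peatland water-balance models (what
drives runoff, ET and storage, and in which direction) without
reproducing any particular published equation set.  All constants sit in
one frozen `HydroParams` block so alternative forms can be swapped.

## Landscape projection

Slope and aspect come from Horn's third-order finite differences on the
8-neighbourhood; borders use one-sided differences via linear
extrapolation padding.  Aspect is the downslope compass bearing (0° =
north, clockwise), the standard GIS convention; flat cells carry slope 0
and the sentinel aspect 0.  Cells are retained if their habitat is heath
or rough grassland (case-insensitive) **and** elevation ≥ 250 m.

Binning uses left-closed, right-open intervals anchored at 0, with the
interval midpoint as the representative (an unbiased within-bin choice;
interval closure and representatives are not fixed by convention, so
both are configurable in principle via the `BinScheme`).  Two schemes:
`landscape` (50 m / 10° / 1°) and `birds` (50 m / 15° / 2° below 20°
slope, 5° above).  An `exact` scheme keeps every distinct topography as
its own bin; with it, binned projection reproduces cell-by-cell
simulation bit-for-bit, which the tests assert on a 20 x 20 DEM.
Aggregation is the arithmetic mean over retained cells, with 1-km survey
squares defined half-open on cell centres so squares partition the grid.

## Trophic statistics

The cranefly model is a negative-binomial (NB2) log-link GLM of quartet
counts on the previous summer's (Jul–Sep) mean WTD plus a three-level
region factor, treatment-coded with the alphabetically first level as
reference.  θ is estimated by the standard alternation: IRLS at fixed θ
(statsmodels `GLM`), then a profile maximum-likelihood update of θ at
fixed means, to a relative tolerance of 1e-8 (cap 100 iterations).  The
null deviance is evaluated at the full model's θ so the deviance
explained, `(null - residual)/null`, is well defined.  An independent
cross-check in the tests refits the same data with statsmodels' joint-ML
NB estimator (a different estimation route) and matches coefficients
and θ.

Other links: OLS for soil moisture on WTD (intercepts, slopes, t, R²,
F); per-species NB GLMs of bird counts on modelled cranefly abundance
(single-year or pooled across the two survey years, with no year term in
the pooled fit); Spearman rank correlations between survey years;
persistence categories (empty / extinct / colonised / occupied) from
presence in each year; tie-corrected Kruskal–Wallis tests and pairwise
two-sided Wilcoxon rank-sum tests (exact when the smaller group has ≤ 25
observations and no ties, otherwise normal approximation with continuity
correction), summarised by an insert-and-absorb compact letter display
at α = 0.05.  Pairwise p values are unadjusted by default — differences
are read at a plain P < 0.05 threshold — with Holm or Bonferroni
available as options.

The spatial robustness check refits the bird model as an NB additive
model with penalised cubic B-spline smooths of the x and y coordinates
(statsmodels `GLMGam`, θ fixed at the plain GLM's estimate).  This is an
additive spatial surface rather than a tensor-product thin-plate smooth;
its contract here is only to show whether the cranefly coefficient moves
materially once smooth spatial trends are absorbed, for which an
additive basis suffices.

Counts are modelled per quartet (four traps of ~0.11 m² each); an
optional conversion to craneflies per m² divides by the sampled quartet
area `QUARTET_AREA_M2 = 0.44 m²`, since trend slopes are most naturally
quoted per m².

## Scenario engine

Future forcing is built from overlapping 30-year periods stepping by 10
years (2010–2039 … 2070–2099).  For each period an ensemble of monthly
realizations is drawn around the period's normals — gamma-distributed
precipitation (mean = normal, configurable CV, default 0.3) and normal
temperature (s.d. default 1 °C).  This is a transparent stand-in for a
full weather generator: it reproduces means and marginal variability but
not day-to-day persistence, inter-variable correlation or spatial
coherence.  Realizations are ranked by mean summer (Jul–Sep) rainfall,
ties broken by realization seed for determinism, and the ⌈n/2⌉-th driest
(the 50th of 100) is the period's approximate median run.  The middle
decade of each selected run is spliced into one continuous series (70
years from seven periods), every month bit-identical to its source.
Annual landscape means are aggregated to decadal means (anchored at the
baseline start year), regressed on decade midpoints (slope per calendar
year), and mapped as 30-year-window changes with the one-year offset
from summer water table to next spring's emergence applied.  The
landscape percent change compares aggregate means of the two windows,
which is not the mean of per-cell changes; the tests document the
distinction.

## Synthetic data: what it does and does not emulate

The generators are pure functions of (parameters, seed) and mirror the
study design: 128 cranefly quartets split across three regions; 557
1-km bird squares; regional annual rainfall targets of 2071 / 1359 /
1016 mm (west–east gradient); winter-wet seasonality (amplitude 0.35)
and a summer-warm temperature sinusoid (mean 6.5 °C, half-range 5.5 °C)
typical of upland Britain.  Cranefly counts are NB2 with the fitted
model's coefficients as generating defaults and θ = 2; bird counts use
configurable log-linear coefficients with θ = 1.5 and a shared
square-level normal effect (s.d. 0.8) that produces between-year
Spearman correlations in the observed moderate range (~0.4–0.6).  θ
values are visibly over-dispersed choices; no dispersion is printed for
the originals.  Dipwell observations add a systematic offset (default
-2.8 cm) plus noise; "manual" sampling adds extra within-month variance
over automatic monthly means.

What passing tests show is internal consistency — the estimators recover
the models that generated the data, the hydrology obeys its balance and
monotonicity properties, and the cascade transmits a drier/warmer signal
end-to-end.  They do not show that the water-balance constants are
calibrated to any real bog, nor that real cranefly or bird populations
follow the generating models; real data would be needed for that.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: recovery
experiments use n = 5000 count sites (50 replicates), landscape checks
use 15–20-cell-square DEMs, cascade checks use 7–8-year forcings with
five seeded replicates.  Deficit/WTD inversion is analytic; θ profiling
is bounded on the log scale in [1e-4, 1e7]; rank-deficient designs and
non-integer counts are rejected; degenerate cases (all-identical
rank-test data, zero-variance predictors, empty masks) raise rather than
return silently.

## Known limitations

- One-dimensional columns: no lateral routing, so wet hollows and
  drained ridges are represented only through topographic binning.
- The PET index and runoff coefficient are deliberately simple; they are
  monotone in the right drivers but not calibrated to eddy-covariance or
  gauging data.
- The weather stand-in has no autocorrelation or precipitation/
  temperature coupling.
- The spatial GAM check uses additive smooths, not an isotropic 2-D
  thin-plate surface.
- Bird generating coefficients are plausible stand-ins; no printed
  coefficients exist to pin them.
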