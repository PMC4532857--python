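# bogcascade

Blanket bogs are rain-fed deep-peat ecosystems whose persistently high
water tables sustain a food chain with a conspicuous bottleneck: cranefly
(Tipulidae) eggs and larvae live in the upper peat and die when it dries
out, and craneflies in turn are a key breeding-season food for upland
waders and gamebirds such as dunlin, golden plover and red grouse.  A
warmer, drier climate therefore threatens these birds not directly, but
through the hydrology of the peat beneath them.

`bogcascade` implements that causal chain as a tested, fully synthetic
pipeline for ecohydrologists and conservation modellers:

1. **Water tables** — a monthly one-dimensional water balance for a peat
   column.  Precipitation enters; runoff (growing with slope, shrinking as
   the water table deepens) and evapotranspiration (a temperature index
   adjusted for elevation lapse and aspect, throttled below the rooting
   zone) leave; a depth-dependent specific yield
   `s(z) = max(s_min, s0 e^{-z/z_s})` converts the stored deficit to a
   water-table depth (WTD, cm; positive below the surface, negative =
   ponding).  Plant functional types respond to the long-term mean WTD and
   feed back on rooting depth.
2. **Landscapes** — slope/aspect/elevation from a 10 m DEM (Horn's
   method), masking to heath / rough grassland above 250 m, and
   topographic binning (50 m x 10° x 1°, or a coarser scheme for large
   bird-survey extents) so one column run per bin covers the landscape.
3. **Trophic links** — negative-binomial log-link GLMs:
   `E[craneflies] = exp(b0 + b_region + b1 * WTD_summer)` with the
   dispersion parameter θ profiled out as in `MASS::glm.nb`, an OLS
   soil-moisture check, bird-count GLMs on modelled cranefly abundance
   (with a spatial GAM robustness check), square-level persistence
   categories (empty / extinct / colonised / occupied) compared by
   Kruskal–Wallis and pairwise Wilcoxon rank-sum tests.
4. **Scenarios** — stochastic 30-year monthly climate ensembles, selection
   of the median (50th driest of 100) run per period, splicing of middle
   decades into a continuous 70-year forcing, decadal trend regressions
   and 30-year-window change maps.
5. **Synthetic data** — seeded generators for every input (terrain,
   habitat, climate along the west–east rainfall gradient, cranefly and
   bird counts, noisy dipwells), so the whole chain runs and is testable
   without any proprietary climate, elevation or survey products.

## Worked example

```python
import numpy as np, pandas as pd
import bogcascade as bc

# 1. synthetic climate and a hillslope point
clim = bc.make_climate(1359.0, years=8, seed=11)   # South-Pennines-like
topo = bc.TopographicCell(slope_deg=5.0, aspect_deg=90.0, elevation_m=420.0)
wtd = bc.simulate(clim, topo)
y = int(clim.year[-1])
print(f"summer mean WTD ({y-1}): {bc.summer_mean_wtd(wtd, y):.2f} cm")

# 2. cranefly quartet counts at 128 sites and the NB GLM
rng = np.random.default_rng(5)
w = rng.uniform(0, 15, 128)
regions = np.array(sorted(("MidWales", "NorthYorkMoors", "SouthPennines")),
                   dtype=object)[np.arange(128) % 3]
counts = bc.make_cranefly_counts(w, regions, seed=6)
fit = bc.fit_negbin_glm(counts, pd.DataFrame({"wtd_cm": w, "region": regions}))
print(fit.coef.round(3).to_string())
print(f"theta = {fit.theta:.2f}, deviance explained = {bc.deviance_explained(fit):.1%}")

# 3. project abundance at two water tables
for d in (2.0, 10.0):
    print(f"expected quartet count at {d:.0f} cm: {float(bc.predict_cranefly(d, fit)):.1f}")
```

prints

```
summer mean WTD (1967): -1.20 cm
                        estimate     se       z      p
(Intercept)                5.443  0.181  30.062  0.000
wtd_cm                    -0.349  0.018 -19.465  0.000
region[NorthYorkMoors]    -0.317  0.180  -1.763  0.078
region[SouthPennines]     -0.232  0.178  -1.305  0.192
theta = 1.85, deviance explained = 72.8%
expected quartet count at 2 cm: 115.0
expected quartet count at 10 cm: 7.1
```

The simulated hillslope ponds slightly (-1.2 cm) in this wet run of the
previous summer.  The refitted GLM recovers the generating coefficients
(intercept 5.203, WTD slope -0.333) within their standard errors at
n = 128, and the log link turns an 8 cm deepening of the summer water
table into a ~16-fold drop in expected cranefly abundance — the
sensitivity that propagates up the food chain.

A command-line entry point `bogcascade` wraps the same functions
(`synth`, `simulate-wtd`, `validate`, `project-landscape`,
`fit-cranefly`, `birds`, `run`); `bogcascade run --seed 1 --out out/`
executes the full synthetic pipeline and writes a reproducibility
manifest next to its outputs.

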