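# Methods

This document records the model equations, parameter defaults, numerical
choices and known limitations of `larvadrift`. Units are degrees of
longitude/latitude for positions, degrees/day for velocities, days for
time, metres for depth and kilometres for distances (haversine on a
sphere of radius 6371 km).

## 1. Probe displacement cycles and raw velocities

A probe cycle is (dive point `x`, resurface point `y`, drift duration
`t`, drift depth). Its raw velocity observation is

    v = (y - x) / t        (deg/day, both components)

attributed to the chord midpoint `X = (x + y)/2`. Ingestion drops
malformed rows (missing coordinates, non-positive durations) and counts
them. Cycles are filtered to a study region (default 143–184°E in the
0–360° frame, 25°S–1.5°S) and a drift-depth band; the canonical analysis
band is 800–1400 m, with 1400–2500 m as the deeper alternative.

## 2. Field reconstruction (iterative optimal interpolation)

Grid: regular lon/lat nodes at 0.1° spacing `h` (configurable).

**Initial field.** Raw velocity observations are interpolated to the
nodes with a C1 cubic triangle-based interpolant
(`CloughTocher2DInterpolator`); nodes outside the convex hull take the
nearest-observation value. At least three non-collinear observations are
required.

**Iteration** (default 3 passes). For each cycle, the dive point is
advected through the current field estimate for the cycle duration,
giving a predicted resurface point `y_b` and model velocity
`v_b = (y_b - x)/t`. The residual `dv = v - v_b` is spread onto the grid
through three Gaussian kernels with scale `h` anchored at the simulated
track's start, midpoint and end, truncated at radius `3h`. Each node
accumulates kernel-weighted residuals from all cycles and updates by

    u <- u + alpha * (sum_n w_n dv_n) / (sum_n w_n)

where `alpha = 1 / (1 + (sigma_o/sigma_b)^2)` with observation-to-
background error ratio `sigma_o/sigma_b = 0.1` (`alpha ≈ 0.990`). The
normalisation by the summed kernel weights (rather than the raw cycle
count) is a deliberate design choice: it makes the update an unbiased
local weighted average, so a node touched by a single distant kernel
tail is not diluted by unrelated cycles. Nodes with negligible total
weight are left unchanged.

**Ensembles.** The observations are thinned before each reconstruction:
every 4th grid square in both directions is selected (1/16 of squares,
random lattice phase), and one random observation is kept per selected
square. Repeating with independent draws (default 500 members; member
`i` is seeded from `SeedSequence([master_seed, i])`) yields an ensemble
whose spread reflects the sampling uncertainty of the probe data.

**Coastal correction.** Given a land mask, a velocity vector at a sea
node whose nearest-direction 8-neighbour is land is rotated to the
angularly closest sea-neighbour direction, preserving its magnitude
(zeroed if the node has no sea neighbour). The correction is idempotent.

Verification targets: simulating retained cycles through the
reconstructed field reproduces their resurfacing points with median
error ≤ 0.01°; across replicate synthetic experiments the assimilation
lowers the RMS velocity error relative to the initial interpolant in
≥ 90% of cases.

## 3. Particle tracking

Trajectories follow `dr/dt = u(r)` in degree coordinates, integrated
day-by-day with adaptive RK23 (`rtol 1e-6`, `atol 1e-8`); the velocity
field is evaluated by a node-exact bicubic spline. Each particle draws
`fields_per_particle = 5` ensemble members without replacement and
switches uniformly among them each day, making the daily field choice
the only time dependence. Release points are abundance-weighted over the
source stations with isotropic Gaussian scatter (SD 0.1°). Default
cohort: 10 000 particles for 500 days with report times 50/100/250/500.
A particle reaching the grid boundary keeps its partial track (status
`left_domain`); summaries use its last recorded day. All draws happen
up-front in particle order, so results are bit-reproducible for a given
seed regardless of integration batching.

Accuracy invariants: 500-day solid-rotation orbits conserve their radius
to better than 0.1%; uniform flow reproduces the exact displacement.

## 4. Planktonic larval duration (PLD)

Across species `i` and observations `j`,

    ln PLD_ij = beta0 + u_i + beta1 z_ij + beta2 z_ij^2 + eps_ij,
    z = ln(T / 15 degC),   u_i ~ N(0, tau^2),   eps ~ N(0, sigma^2)

fitted by REML (`statsmodels` MixedLM) after removing three documented
outlier species. Species intercepts are the standard shrinkage
predictors `u_i = tau^2 / (tau^2 + sigma^2/n_i) * mean residual`
(cross-checked against MixedLM's BLUPs to 1e-13). The reference
temperature response uses the largest lecithotrophic species intercept,
3.54 with the published coefficients `beta = (2.95, -1.30, -0.26)`
(SEs 0.11/0.06/0.05, `tau^2 = 0.92`, `sigma^2 = 0.03`): 34.5 days at
15 °C, ~26.6 days at 18 °C (197 m) and ~152 days at 2.6 °C (1620 m).

**Intervals.** The default 95% interval propagates only the
fixed-effect estimation uncertainty (Monte-Carlo draws from the
coefficient covariance) about the chosen species intercept. This is a
deliberate default: once a species' intercept is fixed, the
between-species variance does not belong in that species' curve, and the
pure residual describes observation scatter rather than curve
uncertainty. Both extra terms can be switched on
(`include_species_variance`, `include_residual`). With the published
SEs this gives ≈ 21.5–33.1 days at 197 m and ≈ 100–233 days at 1620 m.

**Station temperatures.** In the absence of an in-situ climatology file,
temperature at a station's maximum sampling depth comes from a
monotone (PCHIP) interpolation of a standard western-tropical-Pacific
profile (28 °C surface, 18 °C at 200 m, 4.5 °C at 1000 m, 2.6 °C at
1600 m, 1.9 °C floor). A per-station temperature table can override it.

## 5. Connectivity summaries

- Displacement from release and cumulative daily path length, summarised
  per report time by the median and the 2.5th/97.5th percentiles
  (linear interpolation).
- Pairwise population separations by archipelago pair, including
  within-group distinct pairs; singleton groups yield flagged undefined
  within-group rows.
- Habitat crossing: the fraction of particles whose whole-day positions
  enter cells whose seafloor depth lies in the 200–1600 m band
  (ETOPO sign convention, negative = below sea level), evaluated by
  nearest-cell lookup. Positions are sampled at whole days only,
  matching the daily switching granularity.

## 6. Synthetic data generators

Real probe archives, station tables and temperature climatologies are
not bundled; `synthetic_fixtures` provides labelled synthetic stand-ins
whose *defaults encode the documented study conditions*, fixed before
any test outcome was observed and never tuned afterwards:

- probe census strata: 225 cycles shallower than 800 m, 4915 at
  800–1400 m, 4723 at 1400–2500 m, 13 below 2500 m;
- station structure: 17/50/56 locations for New Caledonia/Vanuatu/
  Solomon Islands, clustered at the expeditions' approximate centres
  (165.9°E 21.7°S, 167.1°E 15.9°S, 160.2°E 8.9°S; scales
  0.65/0.65/0.95°), 1070 specimens in total, sampling depths spanning
  197–1620 m with the extremes pinned;
- PLD records drawn exactly from the generative mixed model above;
- analytic velocity fields (uniform, solid rotation, linear,
  double-gyre with peak speed 0.065 deg/day ≈ 8 cm/s) with closed-form
  or tight-tolerance (`rtol 1e-9`) trajectory endpoints as oracles;
- conical-island coast/bathymetry whose polygons agree exactly with the
  elevation sign.

The bundled `data/chiton_station_counts.csv` reproduces the published
per-archipelago station counts for 18 chiton species (richness 4/17/15).

## 7. Scaled problem sizes

The acceptance script and tests run the full pipeline at sizes chosen
for a single CPU, stated here as the package's scaled study conditions:
reconstruction on a 20°×16° domain at 0.4° spacing from 1500 synthetic
cycles with a 25-member ensemble; cohorts of 500 particles for 500 days;
PLD recovery over 100 refits of 20 species × 5 records. The full-scale
defaults (0.1° grid, 500 members, 10 000 particles) remain the
production configuration.

## 8. Limitations

- Degree-coordinate advection ignores the metric convergence of
  meridians (a ~2–4% speed distortion at the study latitudes) and any
  vertical motion; larvae are passive and depth-keeping.
- The reconstruction assumes the deep flow is steady over the averaging
  period; eddies faster than the cycle duration alias into the ensemble
  spread.
- The climatological temperature profile is a single representative
  column; regional hydrographic structure is not represented.
- Habitat crossing uses whole-day positions and nearest-cell bathymetry;
  sub-daily or sub-cell encounters are not interpolated.
- Synthetic stand-ins reproduce documented *composition* (counts,
  strata, cluster geometry), not the true spatial structure of the
  unavailable archives; quantities that depend on the real current field
  (e.g. absolute dispersal distances) are order-of-magnitude realistic
  only.
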