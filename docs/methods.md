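# Methods

## 1. The emission-factor observation model

One observation is one fertilization experiment reporting cumulative N₂O-N
fluxes from a treated plot and an unfertilized control plot over the same
period, plus the N applied:

    EF₁ᵢ = (N₂O_Tᵢ − N₂O_Cᵢ) / Nᵢ   (dimensionless; may be negative)

Units are fixed at kg N₂O-N ha⁻¹ period⁻¹ for fluxes and kg N ha⁻¹
period⁻¹ for N input; the package performs no unit conversion (converting
from g m⁻² or from N₂O molecular mass is the caller's job — see the CSV
schema in `soiln2o.dataset.OBSERVATION_COLUMNS`). A missing control flux is
a filter reason (`NO_CONTROL`), never a zero default: an EF without a
control baseline is not defined.

**Inclusion filters.** Non-peer-reviewed, lab/greenhouse/model, flooded
rice, grazed excreta, enhanced-efficiency fertilizer and organic-soil
records are excluded with one reason code each, in that precedence order.
Missing provenance flags pass with a warning rather than excluding silently,
to keep the filter auditable.

**Covariate classes.**

| factor | classes | boundary rule |
|---|---|---|
| climate | wet / dry | temperate–boreal: precipitation:PET ≥ 1 → wet; tropical: precipitation ≥ 1000 mm → wet. Equality is assigned to the *wetter* class; configurable (`climate_boundary`) because published definitions use strict inequalities in both directions and leave ties open. |
| fertilizer form | synthetic_mixed / organic | mixtures group with synthetic (empirically indistinguishable) |
| N rate | (0;100], (100;200], (200;300], >300 kg N ha⁻¹ | left-open, right-closed |
| irrigation | irrigated / rainfed | defined for dry-climate observations only |
| land cover | annual_bare / perennial | `undefined` raw crops group with annual/bare |
| texture | fine / medium_coarse | fine = sandy clay, silty clay, clay (USDA) |
| soil C | high / low_medium | ≥ 2% → high |
| alkalinity | basic / acid | pH ≥ 7 → basic |
| length | ≤120, (120;180], (180;240], (240;300], >300 d | left-open, right-closed |

A missing covariate makes the observation unclassifiable for that factor
only; it still enters every other factor's model (so per-factor n differs).

**Locations.** Observations with exactly identical coordinates, or from the
same reference with the same soil type and land cover, are one location
(transitive closure of both rules; coordinate identity takes precedence in
the sense that it links records regardless of reference). Missing values in
the reference rule match each other, a deterministic choice documented here
rather than guessing. Identifiers are labelled by the smallest member
record_id, which makes them stable across row orderings.

## 2. The per-factor mixed model

For each factor, EF₁ is modelled as a one-way fixed classification with a
location random intercept, estimated by REML (statsmodels `MixedLM`):

    EF_ij = μ_k(i) + u_loc(i) + ε_ij,  u ~ N(0, σ²_loc),  ε ~ N(0, σ²_res)

Choices where the published analysis names only its software:

* **Estimation.** REML for variance components; AIC from a separate ML
  refit so models with different fixed effects are comparable. Whether the
  original AICs were REML- or ML-based is unknowable from the text; the ML
  convention is standard and is what the package's own comparisons use.
* **Degrees of freedom.** Residual df = n_obs − n_classes −
  (n_locations − 1), a containment-style approximation, used for both the
  CIs (mean ± t(df, 0.975)·SE) and the LSD tests.
* **LSD Fisher.** Unadjusted pairwise t tests with SE of the difference
  from the fixed-effect covariance. Letters are the maximal cliques of the
  non-significance graph ordered by ascending class mean ("A" contains the
  lowest mean); a class may carry several letters when transitivity fails.
  Two classes share a letter iff their pairwise p ≥ α.
* **R².** Squared Pearson correlation between observed EF and fitted values
  *including* predicted random effects. The source text conflates "RMSE"
  and "R²" and does not say whether fitted values include the random
  effects; this definition is the package's own and on realistic synthetic
  data lands in the 0.4–0.5 band the original tables report. Constant
  fitted values → R² undefined (NaN).
* **Small classes.** Classes with n ≤ 20 (configurable) are dropped with a
  warning before fitting; fewer than `min_classes` remaining raises
  `UnanalyzableFactorError`. `min_classes=1` permits a single-class
  (grand-mean) fit.
* **Degenerate fits.** Zero residual variance (or a singular random-effects
  covariance inside statsmodels) raises `SingularFitError`; variance
  estimates are clamped at 0 if an optimizer ever returns a negative value.
* **Merging.** `merge_classes` collapses candidate classes iff all their
  pairwise LSD tests are non-significant, returning an auditable record
  (p values and mean differences). Re-running on merged output is a no-op.

## 3. Triangular EF uncertainty and the Monte Carlo inventory

**Parameterization.** Each stratum's EF is triangular(lower, mode, upper)
with lower/upper = the 95% CI bounds and mode = the reported mean. This
choice is validated by arithmetic: under the single 2006 distribution
(0.003, 0.010, 0.030) the analytic 97.5% quantile 0.0263258 times the
103,010 Gg N worked-example total gives 2,711.8 Gg N₂O-N, matching the
published global upper bound (2,712.7) to a fraction of a percent.

**Draw correlation.** Each Monte Carlo iteration draws ONE value per
*distinct* triangular distribution and applies it to every cell and stratum
using that distribution; distinct distributions are independent. Under
GL2006 (one distribution everywhere) the global CI is therefore exactly
N_total × the EF quantiles; under MR2019 there are three independent draws
(dry, wet-synthetic, wet-manure), with dry synthetic and dry manure sharing
the dry draw. Fully independent per-cell draws would collapse the global CI
by averaging and cannot reproduce the published ranges; the shared draw
does, so it is the structure the package implements.

**Known caveat.** The published *lower* GL bounds (539.1/364.4/174.7 Gg)
sit about 1% above the analytic 2.5% quantiles (532.9/360.2/172.8). The
package matches the analytic oracle; the residual discrepancy is consistent
with Monte Carlo error in the original analysis (its iteration count is not
stated) and is asserted nowhere.

**Aggregation.** Point estimates use mode EFs (the published point
estimates are exactly mode-EF arithmetic: 0.010 × 103,010 = 1,030.1).
Country totals are summed from member cells within each iteration and the
global total from countries, so conservation holds draw by draw to floating
tolerance. Quantiles use linear interpolation between order statistics
(`numpy.quantile` default). Default 100,000 draws; the seed is mandatory.
Units are Gg N throughout, emissions in Gg N₂O-N; × 44/28 conversion to Gg
N₂O is available (`to_n2o_mass`) but never applied by default. Climate is
carried per cell, so countries may be mixed wet/dry. Unknown or malformed
country codes are collected under the sentinel `XXX` with a warning.

**Grid format.** Cell lists are CSV with columns
(cell_id, country_code, climate, n_synthetic_gg, n_manure_gg,
rice_excluded). Raster (GeoTIFF) I/O is out of scope in this build — the
raster libraries are not part of the supported environment and the tabular
cell list is informationally equivalent; flooded-rice exclusion and climate
classification of cells happen upstream of this package.

## 4. Synthetic data: what it emulates, what it does not

**EF observations** (`generate_ef_observations`). EF is drawn from the
(climate × fertilizer form) class structure with true means
wet-synthetic 0.016, wet-organic 0.006, dry 0.005 (both forms), location
variance 2×10⁻⁴ and residual variance 4×10⁻⁴; covariate marginals follow
the published dataset description (76% wet, 80% synthetic, n = 848,
region/texture/soil C/pH/length shares as reported). Fluxes are
back-computed from the drawn EF with the control flux fixed at 1.0 kg
N₂O-N ha⁻¹ — arbitrary but harmless since only EF enters downstream — so
`compute_ef` round-trips the drawn value to machine precision.

Two distribution options:

* `normal` (default): additive Gaussian effects — exactly the structure the
  mixed model assumes. This is deliberately idealized; it is what
  parameter-recovery and CI-coverage tests must exercise.
* `lognormal`: per-class log-normal with the same mean (median =
  mean/exp(σ²/2), log-sd 1.2, location/residual log-variances split 1:3).
  The log-sd was chosen a priori so that, at the stated class shares, about
  70% of EF values fall below 0.01 with a long right tail — the shape real
  EF compilations show.

Not emulated: spatial autocorrelation, crop-specific structure, reporting
artifacts, or the real dataset's exact covariate joint distribution. A green
parameter-recovery test therefore establishes that the estimator recovers
the stated generative truth, not that it reproduces the original tables —
those require the deposited dataset, which is out of scope.

**Fertilizer grids** (`generate_fertilizer_grid`). Cells are assigned to
countries (every country gets at least one cell) and to wet/dry climate by a
target fraction; N masses are log-normal per component and can be rescaled
per stratum to hit exact totals. `worked_example_grid()` is the fixed
400-cell, 10-country grid carrying the global-2000 emulation totals
(48,536/21,084 wet/dry synthetic, 24,350/9,040 wet/dry manure Gg N). Those
totals were *derived* from the published global point estimates by
equating mode-EF arithmetic (0.016·W + 0.005·(69,620 − W) = 882.0 and
0.006·Wm + 0.005·(33,390 − Wm) = 191.3); the true wet/dry split of
year-2000 consumption is not printed in the main text. The grid reproduces
all six published global point estimates to 0.1 Gg and is not a map of real
fertilizer use.

## 5. Numerical and design notes

* Triangular inverse CDF is closed-form piecewise-quadratic; degenerate
  distributions (lower = upper) are point masses. Negative lower bounds
  require an explicit `allow_negative=True`.
* Cell-scope CIs are computed in 64-cell chunks to bound memory at
  ~chunk × n_draws floats.
* Percent differences keep full precision internally; summary tables round
  half-away-from-zero to integers. A zero reference emission makes the
  percent undefined (NaN), never ±inf.
* sklearn conventions: `CovariateClassifier` and `StudyFilter` are
  transformers, `FactorEFModel` an estimator with `fit`/`predict`,
  `get_params`/`set_params` and trailing-underscore fitted attributes, so
  they compose with sklearn pipelines. The inventory engine and the
  generators are plain functions over dataclasses — they are not
  fit/predict-shaped and forcing them into estimator form would obscure
  the seed-in, estimates-out contract.
* Known limitations: no multi-factor or interaction models, no nonlinear
  EF–N-rate response, no indirect N₂O pathways, no flooded-rice or grazing
  emission factors, no raster reprojection. These are out of scope by
  design.
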