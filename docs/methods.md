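# Methods

`thermolag` reproduces, end to end and with known ground truth, the
analysis machinery used to estimate short-term effects of heat waves and
cold spells on repeatedly measured blood parameters in a donor cohort:
event definition, individual exposure assignment, additive mixed-model
estimation with lagged exposures, AIC-based definition selection, and
subgroup heterogeneity testing.

## Event definitions

A *heat wave* (*cold spell*) is a run of consecutive days inside a fixed
seasonal window whose daily mean temperature meets a percentile
threshold for at least a minimum duration.

- Windows: warm = May 15 – Sep 15; cold = Oct 1 – Mar 31. The cold
  window crosses New Year: Dec 31 → Jan 1 count as consecutive days,
  Mar 31 → Oct 1 do not.
- Thresholds: the 95th/97th/99th (heat) and 2nd/5th/10th (cold) sample
  percentiles of daily mean temperature, pooled over **all** fully
  covered window instances of the study period, so each definition
  carries a single threshold in °C. Percentiles use linear interpolation
  between order statistics (`numpy.percentile`, `method="linear"`); the
  convention is configurable because the literature is not uniform.
  Partially covered edge windows at the start/end of the record are
  excluded from pooling and detection; including them is the documented
  alternative.
- Durations: at least 2, 3, or 5 days. The canonical catalog has 8 heat
  definitions (HW01–HW08; the 99th-percentile/5-day combination is
  omitted) and 9 cold definitions (CS01–CS09), 17 in all.
- Comparisons are inclusive (≥ for heat, ≤ for cold). Every day of a
  qualifying run is an event day, including the first `D−1` days.
  Missing days break runs — the detector never fabricates persistence.

`detect_events` is checked exactly against an independent brute-force
oracle (membership in any qualifying block of `min_duration`
consecutive qualifying days) on random series, and the catalog obeys the
subset lattice implied by percentile/duration monotonicity.

## Exposure assignment

- PM2.5 at a residence is the inverse-distance-weighted (IDW) mean of
  station values with weights d^(−power) over great-circle (haversine)
  distances, Earth radius 6371.0088 km. Power defaults to 2 (the
  universal default; configurable), all stations contribute unless a
  `max_km` cutoff is set, stations missing a day are excluded for that
  day, and a co-located station (d < 1e-6 km) short-circuits the
  interpolation.
- Per-visit event exposures: single-day indicators `lag0..lag7`
  (`x_lagk` = 1 iff visit date − k days was an event day) and cumulative
  exposures `cum01..cum07`, defined as the **mean** of the single-day
  indicators over days 0..k. The mean (rather than an "any event"
  indicator or a distributed-lag sum) keeps the regression coefficient
  in per-event-day units comparable across window lengths; this is a
  deliberate convention, and `any` would be a drop-in alternative.
- Meteorological covariates (relative humidity, pressure, PM2.5) enter
  every model at lag 0 (visit date).

## The additive mixed model

For blood parameter `y` of donor `i` at visit `j`:

```
y_ij = β0 + β·x_ij + γ'c_ij + f1(RH_ij) + f2(P_ij) + f3(PM_ij) + u_i + ε_ij
u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ²)
```

`x` is one lag-exposure column; `c` holds sex, age (linear), education,
and BMI category; each `f` is a penalized cubic B-spline (P-spline,
second-order difference penalty, basis size k = 10, quantile-placed
knots, sum-to-zero constraint). An optional smooth of time-since-start
(`time_smooth`) is off by default.

Estimation re-expresses each smooth in mixed-model form: the penalty's
null space (the linear trend; the constant is absorbed by the
intercept) joins the fixed effects, and the range space becomes a block
of i.i.d. random effects with variance σ²/λ. The variance ratios (one
per smooth, one for the donor intercept) maximize the profiled REML
criterion on the log scale by L-BFGS-B from three coarse-grid starts
(tolerance 1e-6 relative, max 200 iterations), followed by a short
Nelder–Mead polish so degenerate closed-form cases (balanced one-way
ANOVA) are matched to 1e-6. Successive refits on the same data
(lag-curve rows, definition scans) reuse the previous optimum as a warm
start with the grid restarts skipped — the tolerances are unchanged.

Given the ratios, coefficients solve the penalized normal equations.
The donor block of those equations is diagonal, which the solver
exploits; a fit costs O(nd + md² + d³) per criterion evaluation for d
model columns and m donors, so cohorts of ~50,000 visits fit in well
under a second.

Inference on β is Wald: the SE comes from the fixed-effect block of the
inverse penalized information, `ci95 = β ± 1.959964·se`. Degenerate
designs are handled explicitly: covariate levels absent from a subset
are dropped as constant columns; a constant *exposure* column (no
exposed visits) is a named, flagged failure, not a silent zero.

**AIC.** Definition selection uses −2·(ML log-likelihood) + 2·edf_total
with edf_total = fixed coefficients + Σ smooth edf (trace-based) +
variance parameters. The ML (not REML) likelihood is used because REML
likelihoods are not comparable when the fixed-effect structure changes
across the exposure-definition scan; the AIC is marginal, not
conditional. Both log-likelihoods are reported, evaluated at the
REML-estimated variance ratios.

## Inference sequence

1. Heat models use warm-window visits only; cold models cold-window
   visits only (inclusive bounds).
2. One lag0 fit per definition (8 heat + 9 cold rows); per-definition
   failures are flagged rows, not aborts.
3. Best definition per kind = minimal AIC; ties break by catalog order.
4. Lag curve for the selected definitions: 15 independent refits (lag0–
   lag7, cum01–cum07), one exposure column each.
5. Subgroups at the lag of maximum effect — argmax |β| among
   *significant* single-day lags, falling back to the overall argmax —
   stratified by sex, age group (18–29/30–39/40–49/50–58), and BMI group
   (<18.5/18.5–25/25–30/≥30, lower-inclusive bounds).
6. Heterogeneity is tested two ways and both are reported: a Wald
   chi-square on the joint exposure-by-stratum interaction coefficients
   of a pooled fit (primary; df = usable levels − 1) and Cochran's Q
   over the per-stratum estimates (secondary). Strata with no exposed
   visits are flagged and excluded with reduced df; small strata
   (< 30 observations) are flagged but kept.
7. α = 0.05 two-tailed throughout. No multiplicity correction is
   applied to the scan; a Bonferroni column is emitted for transparency
   only.

## Synthetic data: what it emulates, and what it does not

The generator states a world matching the reference cohort's
descriptive statistics, chosen once:

- **Temperature**: sinusoid + AR(1) noise (marginal SD 2.8 °C, ρ = 0.7)
  with optional episode offsets added on top of the seasonal mean
  (preserving AR(1) stationarity). Annual mean 12.7 °C, amplitude
  16.0 °C, peak day 197 were solved analytically from the two window
  targets (warm mean ≈ 25.9 °C, cold mean ≈ 2.8 °C). The resulting
  event catalogs closely mirror the reference frequencies (e.g. HW05
  ≈ 1% of warm days, CS07 ≈ 8% of cold days) without any tuning to
  event counts.
- **PM2.5**: shared seasonal log-normal field, winter-peaking (cold
  median > warm median), AR(1) day-to-day shocks, persistent station
  offsets, independent station-day noise. No further spatial
  correlation structure — IDW is exercised, not validated spatially.
- **Cohort**: 2752 donors by default, 72.97% male, ages 18–58 with the
  reference age-band weights, education and BMI category marginals as
  tabulated, independent draws (covariate dependence is out of scope).
  Visits are a homogeneous Poisson process (8/year) inside a per-donor
  activity window (exponential, mean 1049 days, truncated to [56,
  3078] days), thinned to a 28-day minimum gap, with at least 3 visits
  per donor — reproducing the reference follow-up spread and ~20
  visits/donor.
- **Outcomes**: Gaussian for all six parameters, mean/SD as tabulated.
  Default variance split: donor intercept 0.80·SD, residual 0.45·SD —
  repeated blood measurements have high intraclass correlation, and
  this split reproduces the order of magnitude of the reference
  standard errors at the reference sample size. Covariate effects are
  modest; three mild nonlinear confounder effects (in RH, pressure,
  PM2.5) are injected and centered. Injected exposure effects are
  specified as (response, definition, lag, effect) tuples.

A green recovery test therefore establishes that *the pipeline
recovers what this generator injects* — unbiased estimates, nominal CI
coverage, correct argmax lag and sign at realistic signal-to-noise. It
does not establish anything about real meteorology (no fronts,
humidity–temperature coupling, or multi-day episode physics beyond
AR(1) persistence), real donor behavior (no informative visit timing,
no covariate drift other than ageing), or non-Gaussian outcome
features.

Time since first visit is exposed in the data; the default model does
not smooth on it (`time_smooth: off`) because the reference
description of its time variable is ambiguous — the switch exists and
no claim is made either way.

## Numerical choices

- Percentile convention: linear interpolation; configurable.
- Optimizer: log-scale variance ratios, clipped to ±30; a failed
  Cholesky during optimization returns a large finite deviance.
- Variance ratios pinned at 0 (or λ = ∞) reproduce OLS exactly
  (to 1e-8 relative) — tested.
- Spline null-space reduction uses a rank-revealing QR after centering;
  ties in quantile knots are nudged apart.
- Rows with any missing model column are dropped listwise and counted.
- All randomness flows through `numpy.random.default_rng` with seeds
  derived via `SeedSequence`; identical seeds give byte-identical
  outputs after serialization.

## Known limitations

- Adjacent single-day lags are only weakly separable: events last
  several days, so neighboring lag indicators overlap (roughly 2/3 of
  event days are preceded by another event day) and each marginal
  refit absorbs part of a neighboring lag's effect. The *location* of
  a lag curve's maximum is therefore a low-margin contrast — expect
  photo-finish ties between adjacent lags in a non-trivial fraction of
  replicates even at large cohort sizes, although the per-lag estimates
  themselves are unbiased. A joint distributed-lag model would resolve
  this but is deliberately out of scope.
- Wald inference has no small-sample (Satterthwaite/Kenward–Roger)
  correction; with very few exposed visits the interaction test can
  drift from nominal (the calibration test runs at a size where it is
  nominal).
- The cumulative-lag metric is a stated convention, not a claim about
  the reference analysis (which does not define its own).
- Smooth terms share a single basis size default (k = 10); no automatic
  basis-dimension checking.
- One residual variance per parameter; no heteroscedasticity by season
  or donor.
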