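# Methods

## Isotope formula chain

Wood carbon isotope ratios are expressed as δ13C (‰ vs V-PDB),
δ13C = (R_sample/R_standard − 1) × 1000. Plant-to-air discrimination is

    Δ13C = (δ13C_air − δ13C_plant) / (1 + δ13C_plant/1000),

and the simple two-term model for C3 photosynthesis links it to the
leaf-intercellular CO2 fraction,

    Δ13C = a (1 − ci/ca) + b (ci/ca),

with a = 4.4 ‰ (slower diffusion of 13CO2 through stomata) and b = 27 ‰
(Rubisco carboxylation fractionation). With Fick's law, A = g_c (ca − ci),
and g_w = 1.6 g_c (H2O:CO2 diffusivity ratio), intrinsic water-use efficiency
is

    Wi ≡ A/g_w = (ca − ci)/1.6 = ca (b − Δ13C) / (1.6 (b − a)),

reported in ppm (≡ µmol mol⁻¹). Assumptions inherited from this model:
mesophyll conductance and post-photosynthetic/leaf-to-wood offsets are not
modelled — they shift levels, not trends, and are too poorly constrained to
parameterize per species; the constants (a, b, 1.6) are configurable in
`IsotopeConstants` for sensitivity checks. Δ13C outside the open interval
(a, b) implies ci outside (0, ca); such states are **flagged, never
clipped**, and trend analyses exclude them by default — silent clipping
would bias trends.

The `wi_from_discrimination` expression is factored as
(ca/1.6)·(b − Δ)/(b − a) so the physical limits are floating-point exact:
Δ = b gives Wi = 0 and Δ = a gives Wi = ca/1.6.

## Atmospheric records

An `AtmosphericRecord` is a strictly increasing calendar series of
(ca ppm, δ13C_air ‰). Lookups interpolate linearly between tabulated years
and refuse to extrapolate. A *constant mode* record (280 ppm, −6.4 ‰ at
every year) serves analyses of material that grew under effectively constant
pre-industrial CO2, e.g. sub-fossil wood; a packaged CSV with that record
documents the schema for user-supplied spliced ice-core/modern series.

## Below-canopy source air

Daytime soil respiration enriches CO2 and depletes δ13C_air near the forest
floor. The excess CO2 decays exponentially with height,
excess(h) = excess₀ e^(−h/λ), and δ13C_air(h) follows from exact two-member
mass balance between above-canopy air and respired CO2
(ca(h)·δ(h) = ca_above·δ_above + excess(h)·δ_resp). Fitting concentration
and isotope profiles independently could violate that balance; deriving the
isotope profile from the mixture guarantees internal consistency. Mean
canopy CO2 uptake is placed at 0.9 × total tree height. Open-grown trees
bypass the correction — their crowns sample well-mixed air.

Default profile parameters — temperate: 25 ppm ground excess, λ = 2 m;
tropical: 40 ppm, λ = 3 m (tropical effects the larger); δ_resp = −28 ‰ —
are package defaults representative of daytime climatology, not measured
values, and are fully configurable. Consequently the percentage by which the
correction lowers developmental trends is a *directional* result here; its
magnitude depends on the profile amplitudes used.

## Trend estimation

**Linear trends.** OLS (slope, SE, two-sided p, R² from standard theory)
with slopes rescaled to the field's reporting units: ppm (100 yr)⁻¹ for age
and calendar year, ppm (10 m)⁻¹ for height, ppm (10 cm)⁻¹ for diameter, ppm
per ordinal step for crown illumination. Degenerate designs (n < 3 or a
constant predictor) raise; a perfectly flat response returns slope 0, p = 1.
Threshold-ladder fits ("age > 50 yr", "height > 2.5 m", …) use strict
inequality; subsets with fewer than 3 usable records are reported
not-estimable rather than dropped. The age-trend analysis excludes trees
shorter than 1 m (strict) to stay clear of the soil-respiration layer; the
boundary tree is kept.

**Smooth curves.** Penalized cubic B-splines (second-difference coefficient
penalty, Eilers–Marx P-spline) with the penalty weight chosen by generalized
cross-validation on a 25-point log-spaced grid searched from smoothest to
roughest, so among equal-GCV fits the smoothest wins (this makes exactly
linear data return exactly the OLS line). Pointwise standard errors come
from the linear-smoother covariance. When group ids are supplied, a
per-group constant offset (random-intercept surrogate) is absorbed by five
backfitting sweeps before the final smooth; offsets are centred to mean zero
for identifiability. Basis size: one segment per four distinct x values,
clamped to [5, 20] segments.

**Predictor comparison and model selection.** Univariate R²/p per predictor
(age, diameter, height, crown-illumination ordinal); all-subsets
main-effects linear models ranked by gaussian AIC (n·ln(RSS/n) + 2(k+1),
constant terms cancel within one data set). The *selected* model is the most
parsimonious adequate one: the smallest predictor set within 2 AIC units of
the minimum (the conventional ΔAIC ≲ 2 indistinguishability band), with
ties broken towards fewer predictors and then lexicographically; the strict
AIC minimizer is reported alongside. Interactions are not searched — with
strongly collinear developmental predictors they are not interpretable at
these sample sizes. Significance stars follow the conventional legend
(* < 0.05, ** < 0.01, *** < 0.001); no multiple-testing correction, matching
standard practice in this literature.

**Cross-species mixed model.** Wi on age + diameter + height + CII with
species random intercepts, REML via statsmodels MixedLM; fixed-effect t- and
p-values are reported. A single species degenerates to OLS with a warning.
Note the sign of the age effect in this model can legitimately oppose the
marginal age trend: age carries almost no information not already in height
and light, so its partial coefficient absorbs only the residual part.

**Time trends.** Per-ring Wi is computed against the year-matched
atmosphere; each tree/study series gets its own OLS slope, and the combined
trend is the weighted mean of per-series slopes with weights proportional to
study-site counts (default 1), so equal weights reproduce the unweighted
mean exactly. The combined SE is √(Σw²se²)/Σw with a normal-approximation
p-value. A pooled P-spline curve (per-series offsets absorbed) accompanies
the linear summary when ≥ 10 distinct years exist. Display-grade smoothing
of individual annual series uses scipy's GCV cubic smoothing spline.

## Synthetic stands

The generator emulates a single-campaign, size-stratified isotope study and
retains its ground truth:

* **Ages** uniform over [3, 120] yr (even coverage of size classes).
* **Height** monomolecular (von Bertalanffy): H(t) = Hmax(1 − e^(−kt)),
  Hmax = 30 m, k = 0.02 yr⁻¹ — so mid-life growth is Hmax·k/2 = 0.3 m yr⁻¹ —
  with multiplicative lognormal noise (sd 0.10) across trees.
* **Crown illumination** is a monotone stochastic function of height
  relative to the canopy: latent 1 + 7·(H/30 m) plus N(0, 0.7), rounded and
  clamped to the ordinal range 1–8. An `open_grown` flag forces full
  exposure for all years (plantation-style open early growth).
* **True Wi** is linear in the drivers: Wi* = β0 + β_height·(H/10 m) +
  β_light·(CII − 1) + ε, with defaults β0 = 35 ppm, β_height = 18 ppm
  (10 m)⁻¹, β_light = 5 ppm per step, ε ~ N(0, 8 ppm). The height and light
  coefficients and the residual sd are the reference study conditions used
  throughout the tests; β0 places pre-industrial Wi in a realistic
  35–140 ppm band. Values that would leave the physical range (0, ca/1.6)
  are clipped with a warning — at the defaults this is a < 10⁻⁴ tail event.
* **Wood δ13C** is rendered by exact inversion of the formula chain
  (Δ = b − 1.6·Wi·(b−a)/ca, then δ13C_plant = (δ_air − Δ)/(1 + Δ/1000))
  against the tree's source air — the below-canopy profile value at
  0.9 × height when a profile is active. Analysing the rendered δ13C under
  the same source-air assumptions returns Wi* to ~1e−12 relative precision,
  which is what makes full-loop exactness testable.
* **Diameter** follows a simple allometry, dbh = 0.8·H^1.5 × lognormal(0.05)
  cm; trees below coring height (1.3 m) have none.
* **Dominant-tree series** reuse the same growth curve per year of life with
  one height factor per tree and a stepwise-deterministic CII trajectory;
  under a constant atmosphere every apparent time trend in these series is
  purely developmental, and with σ = 0 the mid-life slope equals
  β_height × dH/dt by the chain rule (≈ 54 ppm per century at the defaults).

All randomness flows from one explicit seed (default 20170818) through
numpy's `default_rng`; identical seeds give byte-identical CSV output.

What the generator deliberately does **not** emulate: ecophysiological
process detail (photosynthesis, hydraulics, climate signals in δ13C),
interannual climate noise and autocorrelation in ring series, measurement
error structure of mass spectrometry, survivorship/fast-grower bias in who
becomes a dominant tree, and species differences beyond intercepts. Passing
tests therefore demonstrate the *estimators* are correct and the confound
mechanism is real and quantitative — not that any particular field data set
is free of other biases.

## Numerical choices and degenerate inputs

* Missing-ring estimation rounds half away from zero (deterministic,
  symmetric); distance 0 gives 0 missing rings.
* Decadal ring blocks carry their midpoint calendar year with the block span
  recorded; outer-ring averaging uses annual rings only (unweighted mean),
  flags series shorter than the requested n, and is order-invariant.
* Wood δ13C outside [−40, −10] ‰ is rejected; outside [−35, −18] ‰ (the
  typical range of C3 wood) warns only. High-Wi synthetic trees legitimately
  render above −18 ‰, so the generator suppresses that advisory for its own
  output.
* CSV writers emit `repr(float)` values, so round-trips are lossless and
  identical inputs give bit-identical files.
* Atmospheric interpolation is linear (the standard choice for smooth
  ice-core splices at annual resolution).

## Problem sizes

The test suite and the acceptance script run the reference conditions
directly: 200 stands of 150 trees for recovery/coverage/selection rates,
4 dominant trees × 120 annual rings for the confound demonstration, 10⁴
random inputs for the algebraic identity sweeps and 10³ random data sets for
the OLS oracle comparison. The whole suite completes in a few seconds on one
CPU.

## Known limitations

* The canopy-profile amplitudes are representative defaults; quantitative
  correction impacts require site-measured profiles.
* The time-trend combiner weights whole series, not individual observations;
  unbalanced series lengths are reflected only through per-series slope SEs.
* The mixed model fits random intercepts only (no random slopes), matching
  the spirit of the cross-species analysis but not every possible design.
* The P-spline SE band is conditional on the GCV-selected penalty; it does
  not propagate smoothing-parameter uncertainty.
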