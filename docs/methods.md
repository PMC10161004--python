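# Methods

`forestcti` implements a complete thermophilization analysis for repeat-census
forest inventory data — community temperature indices, their demographic
decomposition, derived climate/topography predictors, and a hierarchical
Bayesian spatial regression — together with a synthetic inventory generator
that makes every stage testable without field data.  This note records the
models, the defaults and why they were chosen, and what the synthetic studies
do and do not demonstrate.

## Community temperature index and its decomposition

The community temperature index (CTI) of a subplot at a census is the
basal-area-weighted mean of the species temperature indices of the stems
present:

    CTI = sum_s BA_s * T_s / sum_s BA_s,      BA = pi (DBH/2)^2

Weighting per individual and summing per species are algebraically identical;
the implementation works per individual and the test suite checks it against
a per-species oracle.  Census boundary rules are inclusive: stems at exactly
12.7 cm DBH and exactly 7.32 m from the subplot centre are in; the filter is
applied per census, so a stem crossing the threshold between censuses appears
only at the second census (as a recruit).  Saplings span [2.5, 12.7) cm.

CTI change between censuses is decomposed by rebuilding counterfactual
second-census communities in which one demographic process acts and the other
two are undone (dead trees resurrected at first-census size, growth frozen,
recruits removed, as appropriate).  Each component is
CTI(counterfactual T2) − CTI(T1).  Because a weighted mean is nonlinear in
its weights, the three components need not sum to the total and the package
never asserts additivity; the exact identities it does guarantee (a component
is exactly zero when its process did not act; a single acting process makes
its component equal the total) are enforced in floating point by evaluating
every scenario with the same summation order.

Negative measured growth (second DBH smaller than the first) is retained
as-is in growth scenarios; no correction is applied.  A community with zero
basal area has an undefined CTI, encoded as NaN and dropped from the affected
model fit with a logged count — never imputed.

## Species temperature indices

Three estimators along the mean-annual-temperature (MAT) axis:

* **simple niche mean** — arithmetic mean of MAT at occurrences;
* **modeled niche mean** — density-weighted (trapezoidal) mean of a smooth
  response curve;
* **modeled niche optimum** — grid argmax of that curve, ties broken to the
  lowest MAT.

The response curve is a penalized cubic-spline logistic regression of
presence (occurrence, coded 1) against background climate (coded 0).  Under
case–control sampling the exponentiated linear predictor is proportional to
the ratio of occurrence density to background density, so with a
representative background it recovers the species' relative occurrence
response.  Defaults: basis dimension 10, smoothing penalty 10 (realised
effective df typically 6–8, recorded on the fitted curve), evaluation grid
step 0.1 °C.  The penalty default was fixed once by a recovery study on
Gaussian niches (breadth 2 °C, n = 2,000 occurrences): it keeps all three
estimators within 0.3 °C of the true optimum while leaving a null
(occurrences ≡ background) curve flat at large n.  Recovery guarantees
presuppose that the background range covers the occurrence distribution;
species whose thermal range is truncated by the sampled climate (range-edge
species) have their modeled means pulled toward the interior, which is a
property of the estimand, not an estimator defect.

The modeled niche mean is the default index used downstream; the three
methods correlate above 0.95 across a synthetic species pool, so the choice
is not load-bearing.

## Derived predictors

* **Climate change** over the census interval is the difference of two
  15-year means of an annual series around the first-census year t:
  mean[t−4, t+10] − mean[t−19, t−5].  On a linear trend of slope m this is
  exactly 15 m (window centres t+3 and t−12).  Climate enters the package at
  annual resolution; aggregation from daily sources is upstream of this
  artifact, and the windows are defined on multi-year means, so daily
  ingestion adds no testable content.
* **Annual climatic water deficit** is the sum of positive monthly
  PET − AET (mm); surplus months clamp to zero.
* **Topographic heat load** follows the folded-aspect equation
  HL = 0.339 + 0.808 cos L cos S − 0.196 sin L sin S − 0.482 cos A′ sin S
  with A′ = |180° − |aspect − 225°||, so the index is maximal on
  southwest-facing slopes and aspect-independent on flat ground.  Several
  published variants of this index exist; the constants are exposed in
  `HeatLoadConstants` so any of them can be substituted.
* **Standardization** uses the sample SD, computed once over the analysis
  set; predictors are time-invariant per subplot, so both census rows share
  the transform.  Transforms are retained so standardized effects can be
  mapped back to natural units.
* **Binary coding**: dummy (0/1) or weighted effect coding, where category 1
  is coded 1 and the reference −n₁/n₀ so the observation-weighted codes sum
  to zero and the intercept (and the census-indicator coefficient) estimate
  population means rather than reference-category means.

## Hierarchical spatial regression

The response is subplot CTI at two censuses (k = 0, 1).  The mean structure
contains an intercept, the census indicator, ten standardized/coded
predictors (baseline MAT, precipitation, CWD; their changes; heat load; fire;
insect; conifer basal fraction), and the ten census-by-predictor
interactions — 22 coefficients.  Random effects: an iid subplot intercept
v_ij ~ N(0, d²) and a plot-level spatial field u_i with Matérn covariance

    C(h) = σ_u² (2^{1−ν}/Γ(ν)) (√(2ν) h/ρ)^ν K_ν(√(2ν) h/ρ),  ν = 1 default

over planar plot coordinates in km.  The dense Gaussian-process covariance is
used directly rather than a finite-element GMRF approximation: at desk scale
(≤ a few thousand plots) the exact field is tractable, and the
marginal-likelihood algebra exploits the two-level grouping so each
evaluation costs one plot-level Cholesky (subplot blocks invert in closed
form; the plot field enters through a P×P Woodbury correction).

Priors are flat (improper) on the coefficients.  By default the four
hyperparameters (σ, d, σ_u, ρ) are estimated by maximizing the restricted
log marginal likelihood over their logs (Nelder–Mead; numerical jitter
1e−8 σ_u² on the field diagonal), and coefficient posteriors are the
conditional Gaussians — empirical Bayes, deterministic, with the caveat that
hyperparameter uncertainty is not propagated.  An ensemble MCMC over the log
hyperparameters with log-uniform priors, mixing the conditional Gaussian for
the coefficients, is available as `inference="mcmc"` and does propagate it.
Fixing σ_u = d = 0 collapses the posterior mean to ordinary least squares
exactly, which the tests assert to 1e−8.

Under weighted effect coding (and centered continuous predictors) the
census-indicator coefficient is the population-mean CTI change over the
10-year interval; dividing by 10 gives the per-year thermophilization rate.
Requesting that interpretation from a dummy-coded fit raises an error.

## Synthetic inventory generator

The generator emulates the sampling frame of a national forest inventory:
plots of four circular 7.32 m subplots; Poisson(7) main-class stems per
subplot (matching per-subplot magnitudes of roughly 5.6 survivors + 1.1
deaths over a decade); a 12.7 cm census threshold with a sapling class;
lognormal sizes and growth increments; per-subplot fire/insect flags;
planar-km coordinates (Euclidean distance feeds the spatial kernel, avoiding
geodesy at desk scale).  Communities assemble by multinomial draws with
Gaussian niche weights around an assembly temperature = macroclimate +
heat-load offset + Matérn plot field + subplot offset + census jitter, which
plants both the CTI–temperature association and spatial autocorrelation.

Demographic effect sizes are explicit dials, all zero/neutral by default:
`mortality_niche_bias` adds log-odds of death per °C a species' optimum
falls below the warmed temperature (multiplied in insect-damaged subplots),
`growth_niche_bias` scales growth increments by thermal mismatch, and
fire/insect act multiplicatively on death odds.  Default rates follow the
per-subplot means typical of western-US inventory data (0.63 recruits per
subplot; base 10-y mortality 0.16; mean warming 0.32 °C per decade).
Recruit provenance is planted at 87% baseline saplings / 9% conspecific
seedlings only / 4% not yet germinated.  Note the published per-subplot
means and totals for such data are not mutually consistent (5.6 survivors
per subplot across ~45k subplots does not reproduce the printed total); the
generator targets the per-subplot means.

What the generator does **not** emulate: hexagonal sampling geometry,
coordinate fuzzing, measurement error in DBH, multi-species interactions,
size-dependent mortality, or real climate rasters.  Passing tests therefore
demonstrate internal correctness and statistical calibration of the method
under its own assumptions — not that the effect sizes estimated from real
inventory data are right.

## Calibration studies and problem sizes

The test suite runs the studies at desk scale, chosen once as the smallest
sizes at which the statistical assertions have comfortable power:

* parameter recovery: 50 replicates of 200 plots × 4 subplots simulated from
  the model itself (time effect 0.05 °C, interaction 0.03, σ_u = 0.3,
  ρ = 30 km, d = 0.2, σ = 0.3); mean bias for the planted coefficients is
  required below 20% and 95% credible-interval coverage at or above 85%;
* null calibration: 20 full pipeline runs (80 plots, no planted effects);
  the mean-thermophilization interval must cover zero in at least 90% of
  runs;
* planted mechanism: a mortality-bias-only landscape must yield positive
  mean thermophilization with the mortality variant the largest component —
  the qualitative signature the decomposition exists to detect;
* exact checks: CTI against a brute-force oracle (1,000 communities,
  1e−12 relative), decomposition identities (1,000 subplots, exact), the
  covariate closed forms, the Matérn ν = ½ ↔ exponential limit, and the
  OLS collapse.

`scripts/acceptance.py` re-runs the same computations from scratch under a
caller-supplied seed and writes the resulting numbers to JSON.

## Known limitations

* Empirical-Bayes credible intervals ignore hyperparameter uncertainty; on
  small plot networks they can undercover for the spatial variance itself
  (the coefficient intervals are what the calibration study checks).
* The fitted ρ and σ_u are weakly identified when the plot network is sparse
  relative to the range; the regression coefficients are robust to this.
* The response-curve family (penalized presence/background logistic spline)
  is a standard choice, validated here by recovery properties rather than by
  replication of any particular published fit.
* `decompose` treats an empty counterfactual community as undefined (NaN)
  rather than extrapolating; downstream fits drop such rows and log counts.
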