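# forestcti

Thermophilization analysis for repeat-census forest inventories: community
temperature indices, their demographic decomposition, and a hierarchical
Bayesian spatial regression — with a synthetic inventory generator so the
whole pipeline runs and is tested end to end without field data.

## The problem

As climates warm, forest communities shift toward tree species with warmer
climatic niches ("thermophilization").  Permanent-plot inventory networks —
plots of four circular 7.32 m subplots in which every stem with diameter at
breast height (DBH) ≥ 12.7 cm is measured and re-measured a decade later —
make it possible to measure that shift at fine grain, to ask which
demographic process drives it, and to test what modifies its rate.  This
package implements that analysis for anyone working with such data (or
wanting to study the method's behaviour on simulated data): forest
ecologists, biogeographers, and statisticians interested in
community-weighted-mean dynamics.

## The method

**Community temperature index (CTI).**  For each species, a temperature
index T_s is estimated from occurrences along the mean-annual-temperature
axis (simple niche mean, modeled niche mean from a penalized
presence/background logistic spline, or the curve's modeled optimum).  Each
subplot's CTI at each census is the basal-area-weighted mean
Σ BA_s T_s / Σ BA_s with BA = π(DBH/2)².  Thermophilization is the CTI
increase between censuses.

**Demographic decomposition.**  Counterfactual second-census communities
isolate each process: *mortality* (dead stems removed, survivors frozen at
first-census size, recruits omitted), *growth* (survivors grown, dead kept
alive at first-census size, recruits omitted), *recruitment* (recruits
enter, everything else frozen).  Each component is
CTI(counterfactual T2) − CTI(T1).

**Regression.**  Subplot CTI at both censuses is modeled as

    Y_ijk ~ N(μ_ijk, σ²)
    μ_ijk = β₀ + β₁·time_k + Σ_p β_p x_p + Σ_p β_p' time_k·x_p + u_i + v_ij

with ten predictors (baseline mean annual temperature, precipitation and
climatic water deficit; their 15-y sliding-window changes; topographic heat
load; fire and insect damage flags; conifer basal-area fraction), their
interactions with the census indicator, an iid subplot effect
v_ij ~ N(0, d²), and a plot-level Matérn Gaussian field u_i over plot
coordinates.  Continuous predictors are standardized; binary flags can be
dummy- or weighted-effect-coded — under weighted effect coding β₁ is the
*population-mean* thermophilization per decade.  Hyperparameters are
estimated by restricted marginal likelihood (empirical Bayes) with an MCMC
option.  See `docs/methods.md` for details and defaults.

## Worked example

Simulate a landscape where warming-biased mortality is the only planted
mechanism, then run the full pipeline (niche estimation → CTI and
decomposition → covariates → spatial regression for the total and the three
component responses):

```sh
forestcti run-all --config demo.yaml
```

with `demo.yaml`:

```yaml
outdir: demo_run
seed: 77
simulation:
  n_plots: 100
  n_species: 20
  mortality_niche_bias: 0.4   # log-odds of death per degC of thermal deficit
niche:
  n_occurrences: 300
model:
  variants: [all, mortality, growth, recruitment]
  coding_scheme: weighted_effect
```

which prints

```
mean thermophilization: +0.1948 degC per 10 y [+0.1327, +0.2569] (+0.01948 degC/y)
run-all: complete, manifest at demo_run/run_manifest.json
```

The headline line is the posterior mean and 95% credible interval of β₁ —
the population-mean CTI change over the 10-y census interval — which is
strongly positive because cool-niche trees were made to die preferentially.
`demo_run/effects.json` holds the per-variant summaries: the mortality
variant carries nearly the whole effect (β₁ = +0.204 °C per decade,
CrI [+0.139, +0.268]) while growth (+0.015) and recruitment (−0.000) sit
near zero — exactly the mechanism planted in the generator.  `demo_run/effects.csv` lists all 22
coefficients and the variance/spatial hyperparameters per variant, and
`run_manifest.json` records row counts, dropped observations and timings for
every stage.

Each stage is also available separately (`simulate`, `niches`, `cti`,
`covariates`, `fit`, `validate`), reading and writing plain CSV artifacts,
and everything is importable as a library (`forestcti.community.decompose`,
`forestcti.model.fit`, ...).

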