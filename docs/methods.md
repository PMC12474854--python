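# Methods

`ccxburden` implements the statistical machinery of a nationwide
time-stratified case-crossover analysis of short-term fine particulate
matter (PM2.5) and cause-specific mortality, together with the
attributable-burden arithmetic that translates fitted odds ratios into
excess deaths and years of life lost. Because the registry microdata and
modeled exposure surfaces such studies rely on are access-restricted, the
package ships a synthetic-data generator with known ground truth; every
stage of the pipeline is validated against that truth and against
independent oracles.

## Study design and likelihood

Each death defines a *case day*; its referent (control) days are the other
days with the same day of week in the same calendar month and year. Every
month-weekday stratum over 2015–2019 contains 4 or 5 same-weekday dates,
so each case has exactly 3 or 4 controls. Matching on the stratum removes,
by construction, all confounders constant within a month (age, sex,
district characteristics, slow seasonal and long-term trends) and weekday
effects.

For a matched set with rows j = 1..m (one case), covariate profiles x_j
and coefficients β, the conditional likelihood contribution is the
within-set softmax

    P(case = i) = exp(x_i'β) / Σ_j exp(x_j'β),

and the fitter maximizes Σ_sets [x_case'β − log Σ_j exp(x_j'β)] by
Newton–Raphson with analytic gradient and Hessian, step-halving, and a
convergence tolerance of 1e-8 on the max-norm of the gradient. Columns are
standardized internally (centring is likelihood-invariant in a conditional
model; scaling is a reparametrization) so that the tolerance is meaningful
when cubic spline columns with scales of 10^3–10^4 sit next to an exposure
in μg/m³; coefficients and covariance are transformed back exactly.
Set-constant columns carry no information — their within-set gradient
contribution is identically zero — and are detected and excluded
(coefficient reported as NaN), which realizes the design's self-matching
property exactly. The covariance is the inverse observed information;
intervals are Wald. A numerically perfect fit (log-likelihood at 0) is
flagged as complete separation rather than reported as a finite estimate.

Deaths are kept as individual records: same-day same-district deaths form
separate matched sets, which is likelihood-equivalent to multiplicity
weighting. For district-day Poisson counts with a log-linear rate, the
days-of-death within a stratum are multinomial with exactly the softmax
probabilities above, so the conditional likelihood is the correct
likelihood of the simulated data, not an approximation.

## Model designs

The default design mirrors the main specification of this literature: a
linear term for the lag 0–1 PM2.5 moving average (coefficient per
1 μg/m³; reported as an odds ratio per 10 μg/m³, exp(10β), with Wald 95%
intervals), adjusted for the lag 0–3 temperature moving average through a
natural cubic spline with six degrees of freedom, plus linear relative
humidity and precipitation. A configuration switch splines all three
weather covariates; another adds lag 0–1 NO2 linearly (the two-pollutant
sensitivity model).

The spline basis is the truncated-power natural cubic spline: K total
knots give K−1 columns (no intercept — it would cancel from the
conditional likelihood), each linear beyond the boundary knots. Two knot
placements are used, matching their two roles: for the confounder spline
specified by degrees of freedom, internal knots sit at equally spaced
quantiles of the fitted data with boundary knots at the min/max (knots are
per-fit, i.e. per analyzed stratum); for the nonlinear exposure-response
curve, three internal knots are placed equally spaced over the observed
exposure range. The exposure-response curve reports exp{(B(x) −
B(x_ref))'β̂} against a reference at the minimum observed exposure, with
pointwise Wald bands.

Effect modification enters as PM2.5 × tertile interaction columns (low
tertile as reference); per-category odds ratios combine the main and
interaction coefficients with the full covariance, and the two-sided Wald
tests on the interaction coefficients test "no difference in OR between
categories". District indicators are categorized into thirds by rank
(ties broken by district id), which agrees with type-7 empirical tertiles
for distinct values, always yields groups within one district of each
other, and is invariant to strictly increasing transforms.

Lag selection refits the identical matched sets (sets missing any
candidate column are removed first) with each candidate exposure window
(lag 0–1, 0–2, 0–3) and compares AIC = −2ℓ + 2p; ties break to the
shortest window. No multiple-testing correction is applied across the 45
cause × age strata; per-stratum intervals are reported as is, matching
standard practice in this literature.

## Attributable burden

With a fitted coefficient β per μg/m³ and daily exposure x_t, the relative
risk against a zero-exposure counterfactual is RR_t = exp(βx_t) and the
daily attributable fraction AF_t = 1 − exp(−βx_t); excess deaths are
AF_t × deaths_t, summed over the period. The excess mortality fraction is
that sum divided by *all* deaths, in percent. The guideline-restricted
scope sums excess deaths only over days whose exposure exceeds the WHO
2021 daily value (15 μg/m³, strict inequality), keeping all deaths in the
denominator — so the restricted fraction measures the share of total
mortality attributable to PM2.5 on non-compliant days. By default the
exceedance flag is evaluated on the same lag 0–1 metric used in the
regression, with a switch for raw daily values; a nonzero counterfactual
(e.g. 15 μg/m³) attributes only the exposure increment above it. YLL
weights age-group excess deaths by remaining life expectancy; with the
built-in flat life table YLL is exactly the constant times excess deaths,
which the tests exploit as an algebraic identity. For pooled ("total")
rows the age-specific daily death counts are used with the row's own
fitted coefficient, so YLL reflects the age composition of the deaths.

Uncertainty propagates only the exposure coefficient, as is standard:
draws β ~ N(β̂, SE²) (1,000 by default) are pushed through the burden
functional and the empirical 2.5th/97.5th percentiles reported. Death
counts and exposure are treated as fixed. With SE = 0 the interval
collapses to the point estimate; intervals are deterministic given the
seed.

## The synthetic-data generator

The generator emulates the four inputs the analysis consumes, with
defaults set to the study conditions the package is validated under:
2015–2019 daily series, district-level mean PM2.5 near 25.04 μg/m³, and a
true log odds ratio per μg/m³ of log(1.008)/10.

* **Exposure/weather.** PM2.5 is a district-level mean (SD 3 μg/m³ across
  districts) plus a winter-peaking seasonal sinusoid (amplitude 8 μg/m³)
  plus AR(1) noise (lag-1 correlation 0.5, stationary SD 6 μg/m³),
  coupled to the daily temperature anomaly at −0.3 μg/m³ per °C
  (stagnation-like co-variation) and truncated at zero. NO2 is correlated
  with PM2.5 (r ≈ 0.6). Temperature is a summer-peaking sinusoid
  (mean 12.5 °C, amplitude 11 °C) with Gaussian anomalies (SD 3 °C);
  humidity is seasonal and clipped to [1, 100]%; precipitation is a 30%
  wet-day Bernoulli times an exponential amount. The joint
  PM2.5–temperature structure is not identified by published sources and
  is a modeling choice, exposed in the configuration.
* **Mortality.** District-day counts are Poisson with log-rate
  log(baseline) + β·x + f(T), where x is the centred lag 0–1 PM2.5 mean
  and f a smooth V/J-shaped function of the lag 0–3 temperature moving
  average: linear cold and heat wings (0.012 and 0.03 log-units per °C)
  joined by a 3 °C softplus hinge at a 20 °C optimum. Both terms are
  centred so the realized count stays near the configured baseline.
  Counts are exploded to individual records with age group, leaf cause of
  death and sex drawn from mixture vectors whose defaults reproduce the
  published national shares (circulatory 23.5%, respiratory 12.7%; ages
  14.2/13.1/25.5/47.2% across 0–59/60–69/70–79/80+). The split of the
  circulatory and respiratory totals into their three leaf causes each is
  not published and is a fixed plausible choice. Cause *groups* overlap
  (non-accidental ⊇ circulatory ⊇ ischemic heart …) and are defined as
  sets of mutually exclusive leaf labels. The first three days of the
  series are excluded from case eligibility because the lag 0–1 exposure
  and lag 0–3 temperature windows are undefined there.
* **Indicators and life table.** Four district indicators are independent
  lognormals; an optional per-tertile additive shift on β generates true
  effect modification. The built-in life table is a monotone,
  plausible-magnitude table of remaining life expectancy at age of death
  (40/22.5/13.9/7.2 years); the "total" category carries the
  mixture-weighted average so all five age categories used in reporting
  can be looked up. A "flat" table supports analytic identities.

The wings of the temperature-mortality function are deliberately linear:
a natural cubic spline is linear beyond its boundary knots, so the
generative confounder lies inside the span of the adjustment basis.
During development a globally quadratic temperature effect was found to
leave a replicate-varying residual (its tails are outside any natural
spline's span) that, through the PM–temperature coupling, inflated the
dispersion of the estimator by ~18% relative to its model SE and pulled
interval coverage to ~90%. The V/J shape is both closer to the
temperature-mortality curves reported in this literature and lies within
the adjustment span up to a residual of ~6e-5 log-units, so the
validation suite tests the estimator under conditions where its
assumptions essentially hold. Measured 95%-interval coverage of the true
odds ratio at the full validation scale (~50,000 cases per replicate)
pools to roughly 92–95% across several hundred replicates — at or
slightly below nominal, consistent with mild finite-sample
anti-conservatism of Wald intervals in the spline-adjusted design; with
the temperature effect switched off, measured coverage is nominal.

What the generator does *not* emulate: real spatial exposure fields and
district geography, exposure measurement error (district aggregation is
exact in simulation), harvesting/displacement dynamics, day-of-week
mortality structure, overdispersion beyond Poisson, and within-district
heterogeneity of indicators. Passing tests therefore demonstrate
correctness of the estimator and burden arithmetic under the stated
generative model, not robustness to these real-data complications.

## Numerical choices and degenerate inputs

* Newton–Raphson: max 100 iterations, gradient max-norm < 1e-8, step
  halved up to 40 times; failure to improve the likelihood or a perfect
  fit is reported, never silently accepted.
* Matched sets with any missing required covariate are dropped and
  counted (complete-case by window; no imputation); drops are logged and
  recorded in the run manifest.
* Tertiles are undefined when all values are identical (rejected), and
  require at least three districts.
* AIC ties in lag selection break deterministically to the shortest lag.
* Exceedance uses a strict inequality (> 15 μg/m³); ties have measure
  zero under the continuous exposure model.
* Monte-Carlo seeds: every stochastic stage takes an explicit seed;
  sub-streams are derived with `numpy` seed sequences so re-running one
  stage does not perturb another.

## Validation problem sizes

The frequentist calibration checks run at the sizes a single CPU handles
comfortably: interval coverage of the true OR uses 100 replicates of a
full 2015–2019 study with ~50,000 cases across 10 districts; null
calibration and interaction-p uniformity use 200 single-year replicates
(~2,500 cases each); the likelihood cross-check against a reference
conditional-logit implementation uses 200 matched sets. Model-selection
and curve-recovery checks use 8–10 replicates with binomially consistent
pass thresholds at the corresponding expected rates.

## Known limitations

* Wald intervals throughout (no profile likelihood); at very small
  stratum sizes they can undercover.
* The burden module treats the fitted odds ratio as a rate ratio, the
  standard approximation for rare daily outcomes.
* YLL uses no discounting or age weighting.
* The pipeline fits strata independently; no shrinkage or pooling across
  the 45 cause × age combinations.
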