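# Methods

`costlab` models hospital treatment cost and length of stay (LOS) for
spontaneous intracerebral hemorrhage (ICH) discharge cohorts.  Because
administrative discharge data of this kind cannot be redistributed, the
package pairs every estimator with a calibrated synthetic-cohort
generator: the generator is tuned until the *pipeline's own estimators*
reproduce the published cohort summaries and effect estimates, and the
planted parameters then serve as ground truth for validating the
estimators.  This note documents the models, the generator, the
calibration, and the numerical choices.

## Estimators

### Dollar-scale cost effects

Costs are strongly right-skewed, so association models are ordinary
least squares on the natural log of cost:

    ln C_i = β0 + β_x x_i + β_a age_i + ε_i,

with heteroscedasticity-robust HC1 ("sandwich") standard errors for
inference.  The named statistical software the original analyses used
reports HC1 by default, which is why that variant was chosen.  Log-scale
coefficients are translated to dollars with Duan's smearing estimator,

    s = (1/n) Σ exp(e_i),    E[C | x] ≈ s · exp(x'β),

which corrects the retransformation bias of `exp(fitted)` without a
normality assumption.  The reported `dollar_change` is an **average
marginal effect**: the cohort-average difference between smeared
predictions with the exposure set to 1 versus 0 (or incremented by one
unit for the morbidity count), other covariates at observed values.
Whether published dollar effects of this kind are average marginal
effects or effects at covariate means is generally ambiguous; the
average marginal effect was chosen as the default estimand and the
machinery makes the counterfactual design matrices explicit so the
alternative is easy to add.  Confidence intervals for dollar changes
come from a seeded nonparametric percentile bootstrap (default 1,000
replicates) of the entire procedure — resample discharges, refit,
re-smear, re-average — because no closed-form variance exists for the
smeared average marginal effect.  No multiple-testing correction is
applied by default (each morbidity is tested at α = 0.05, matching the
original reporting); a Holm adjustment is available behind a flag.

### Prolonged-stay relative risks

Prolonged stay is **strictly more than 7 days** (a 7-day stay is
short).  Relative risks come from a binomial GLM with log link.  At the
outcome and exposure prevalences involved (≈50% prolonged stays, 67%
hypertension) the log-binomial likelihood often fails to converge, so
the fit falls back automatically to the modified Poisson estimator
(Poisson GLM with HC1 robust variance), which targets the same risk
ratio; `RRResult.model_used` records the route.  Deaths are not
censored from LOS models.  Calendar trend tests are binomial
regressions of a characteristic on admission year.

### Cost–time curvature

ln(cost) rises steeply over the first hospital days and flattens, so a
straight line in LOS misfits.  Two models are fit:

* a restricted cubic spline (Harrell's truncated-power basis, linear
  beyond the boundary knots) with five knots at the 5/27.5/50/72.5/95
  percentiles of LOS — the knot count and placement follow the standard
  default because the original description states neither — fit
  unadjusted by OLS on ln(cost), reporting R²;
* a continuous piecewise-linear spline with knots every 7 days,
  parameterized in slope-change columns so that "did the slope change
  from last week?" is a robust Wald test on one coefficient, and the
  within-interval slope test is a Wald test on a cumulative sum of
  coefficients.  Intervals with fewer than two observations report NaN
  tests and the fit proceeds.

Reporting windows for cost summaries (first day / first month / first
year) are interpreted as *length of stay within the window*, i.e.
cumulative, overlapping windows; summaries are unadjusted order
statistics.

### Generational Monte Carlo simulation

The sensitivity analysis projects a century of admissions: total
admissions follow `base_population × rate × Σ (1+g)^t` (the base
population is not printed anywhere and was back-solved from the
published century total, growth and rate; ≈36.3 million), ages are
truncated-normal 70 ± 13 on [18, 126], and hypertension is Bernoulli
at 77%.  Each simulated patient receives the *observed* ln(cost) of a
reference-cohort patient resampled (with replacement) from the same
hypertension stratum among the 25 nearest in age — no parametric
assumption about the cost attributable to hypertension or its
variability.  Every replicate refits the age-adjusted smeared model;
the replicate distribution is summarized and may be compared to a
bootstrap distribution of a primary estimate with Welch's
unequal-variance test (Satterthwaite degrees of freedom).  Desk-scale
defaults (1,000 replicates of 20,000 patients) are configurable up to
population scale; what the replicate distribution estimates — the
estimator's sampling behaviour — does not depend on running the full
10⁶ × 717,727 configuration.

## The synthetic generator

Per discharge:

* **age** — truncated normal 72 ± 13 on [18, 99], inverse-CDF sampled
  (no rejection, for seed stability); sex M with probability 0.55;
  admission year uniform on 1999–2008 (calendar-trend knobs default to
  zero).
* **morbidity flags** — Bernoulli at the 13 published admission
  prevalences (hypertension 0.67 … peptic ulcer 0.01).  Dependence
  between categories is modelled with a **latent multimorbid class**: a
  calibrated fraction of discharges (≈8%) belong to a cluster in which
  hypertension is near-universal and every other category is enriched
  proportionally to calibrated weights; within/outside prevalences are
  balanced so each *marginal* prevalence is exact and the any-morbidity
  fraction equals its published 81%.  See "Identifying the dependence
  structure" below.
* **diagnosis codes** — an index-hemorrhage MRDx code plus one
  category-specific ICD-10 code per raised flag, each chosen to match
  exactly one catalog category, so classification round-trips the
  planted profile exactly.
* **length of stay** — discretized log-normal (σ = 1.25 on the log
  scale, truncated to [1, 190] days) whose exceedance probability
  P(LOS > 7) follows a log-binomial model: a calibrated baseline times
  exp(planted log-RRs of the flags, plus a none-vs-some "any morbidity"
  step).  The multiplicative exceedance probability is clamped at 0.97,
  which slightly attenuates the planted effect in the rare heavily
  multimorbid patients — the familiar boundary problem of log-link
  binomial models.
* **cost** — ln(total) = intercept + 0.004·(age − 72) + Σ planted
  morbidity effects + f(LOS) + N(0, σ); f is a monotone concave
  piecewise-linear LOS–cost link with weekly knots (steep first week,
  flattening thereafter, linear tail).  The total is split into
  diagnostic / acute / rehabilitation parts by a log-normally perturbed
  baseline share (0.20/0.55/0.25), so the parts sum to the total by
  construction.
* **outcomes** — in-hospital death is logistic in −ln(LOS) (deaths
  concentrate in short stays; gradient strength 0.5 with the intercept
  solved per cohort for a 28% marginal rate); surgery is Bernoulli
  0.18; NIHSS ≥ 15 and discharge mRS 3–5 are generated for a ≈15%
  severity subgroup, associated with realized LOS but not directly with
  hypertension.

Same seed ⇒ bit-identical cohort.

## Calibration

`calibrate_generator` tunes the free knobs in a damped fixed-point loop
(about 15–20 iterations), measuring each iteration on several pooled
large cohorts with fixed seeds so the frozen constants do not overfit a
single random stream:

| knob | target |
| --- | --- |
| class enrichment scale | any-morbidity fraction 0.81 (closed form) |
| within-class hypertension prevalence | marginal-vs-fully-adjusted hypertension gap |
| class fraction | per-added-morbidity dollar change |
| baseline LOS exceedance | median LOS 8 days |
| cost intercept | median total cost $10,202.73 |
| first-week link slope | one-day-stay median cost $1,909.45 |
| link tail slope | mean total cost $20,165.14 |
| residual SD of ln cost | restricted-cubic-spline R² 0.73 |
| 13 planted cost effects | per-category age-adjusted dollar changes |
| planted LOS log-RRs | per-category marginal RRs; fully adjusted hypertension RR 1.31 |
| any-morbidity LOS step | any-vs-none RR 1.69 |

The published per-category LOS relative risks and cost effects are
*marginal* (age-adjusted only) estimates, so the planted conditional
parameters are tuned until the *recovered marginal* estimates match the
published ones; under clustering the conditional values are smaller
than the marginals, and several direct cost coefficients are negative
because the indirect pathways (stay prolongation, co-occurrence)
already overshoot the published marginal dollar change.

### Identifying the dependence structure

The published material constrains morbidity dependence only indirectly:
the 13 marginal prevalences, the 81% any-morbidity fraction, the pair
of hypertension cost estimates (age-adjusted $10,324.56 vs fully
adjusted $8,123.51 — their difference is pure cross-morbidity
confounding), and the per-added-morbidity estimate ($4,958.36, well
below what independent flags would imply).  Several dependence families
were evaluated against these constraints (a shared Gaussian logit
frailty with equal and with category-specific loadings, and latent-class
structures).  The latent multimorbid class is the only family examined
that reproduces the any-morbidity fraction and the count-model estimate
simultaneously; its hypertension-confounding gap, however, saturates
near $1,000 — under *every* structure examined, pushing the gap toward
the published ≈$2,200 while holding the any-morbidity fraction at 81%
either fails or destroys other targets.  The two hypertension targets
are therefore jointly infeasible at exact equality, and the calibration
resolves this transparently: the marginal anchor is placed so that the
two relative residuals are equal in units of their stated recovery
tolerances (5% marginal, 10% fully adjusted; `balance_htn_targets`).
Both recovered values then sit inside their tolerance bands, a few
percent off-centre in opposite directions, and the remaining shortfall
is a documented property of the generator rather than a hidden bias.

## What the generator does not emulate

* Coding noise: diagnosis codes are exact signatures of the planted
  flags; real abstracts misclassify, so the perfect classifier
  round-trip says nothing about clinical-coding accuracy.
* Within-stay cost accrual: cost attaches to the completed stay, so
  cumulative "cost by day k of the stay" quantities are out of reach.
* Heteroscedastic cost noise: the original data show larger cost
  variability for short stays; the generator's residual SD is constant
  in LOS.
* Calendar drift: prevalence/cost trends over the decade default to
  none.
* Physician fees are not part of the cost concept.

Consequently, passing tests demonstrate that the estimators recover
known structure of this form at these sample sizes — not that the
pipeline is robust to coding error or non-stationarity in real
administrative data.

## Numerical choices

* Truncated-normal and log-normal sampling by inverse CDF; all
  randomness from one `numpy` Generator per cohort.
* Exceedance and within-class probabilities clamped to ≤ 0.97;
  outside-class prevalences floored at 0.
* Link tail slope floored at 10⁻⁴ per day (monotonicity), first-week
  slope bounded below by the second-week slope (concavity).
* OLS via `statsmodels` with HC1 covariance; GLMs limited to 200 IRLS
  iterations; the log-binomial route is rejected if any fitted
  probability reaches 1 or any standard error is non-finite.
* Rank deficiency is reported with the names of removable columns.
* Percentile bootstrap (2.5/97.5) with a seeded generator.
* Weekly-spline tests use normal (z) reference distributions on robust
  variances.
* CPI series ships as an editable two-column CSV (US CPI-U annual
  averages 1999–2015); inflation is the index ratio, so chained and
  direct adjustment agree to machine precision.

### Weekly slope-change tests and multiplicity

The weekly spline reports one slope-change test per interval.  At
n ≈ 987 the local slopes beyond the third week are estimated from a few
dozen discharges each, so their sampling wiggle is of the same order as
the true flattening; asking *every* post-week-3 change test to stay
above 0.05 simultaneously is a joint event over roughly eight noisy
5%-level tests and fails in a sizeable share of cohorts even when the
underlying curve truly is flat after week three.  The qualitative
claim — steep, precisely estimated slopes for the first three weeks,
no systematic change thereafter — is the reproducible statement;
interval tests on fewer than `min_obs` (default 10) discharges are
reported as NaN because heteroscedasticity-robust Wald tests are
strongly anticonservative on a handful of points.

## Known limitations

* The t-statistic reference for robust Wald tests is asymptotic; at
  n < 100 the type-I error of `association_test` drifts above nominal.
* The AME dollar scale is sensitive to the extreme upper cost tail, so
  dollar-effect estimates at n = 50,000 still carry a Monte Carlo SD of
  roughly $100–150; validation therefore averages several cohorts.
* The generational simulation's nearest-age resampler requires both
  hypertension strata in the reference cohort and at least `match_pool`
  patients per stratum to behave as intended.
* `calibrate_generator` assumes its targets are jointly reachable up to
  the documented hypertension-gap saturation; pathological target sets
  raise `CalibrationError` with the residual vector.
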