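# Methods

## Overview

`hot-equity` estimates how differences in active travel (transportation
walking and cycling) across population subgroups translate into
differences in all-cause mortality risk.  The pipeline has five stages:
synthetic survey generation, cohort filtering, survey-weighted
estimation, regression parameterization, and the Health-Oriented
Transportation (HOT) comparative risk assessment.  Every stage lives in
the `hot_equity` library; the `analysis/` scripts and the `hot-equity`
CLI are thin drivers over it.

## The synthetic survey generator

The generator emulates a one-day US household travel survey restricted
to adults.  Structure per draw:

- **Households.** `n_households` households; adult count per household
  is `1 + Poisson(mean_household_adults − 1)` (≥1 adult by
  construction; default mean 1.7 adults, typical of survey adult
  rosters).  Income bracket (8 levels), cars per household (0/1/2/3+),
  census-block population density (8 bins), state, season, and the
  metro-over-1M flag are household-level and shared by members.
- **Persons.** Sex, race (7 categories), Hispanic status, education
  (5 levels) and age (uniform integer, default 18–84 so the age filter
  is exercised on both ends) are person-level.  In `year_mode=2009` the
  household respondent's race and Hispanic status are copied to every
  member, as the 2009 survey instrument recorded them only once per
  household.  Category probabilities default to the 2017-style
  metropolitan sample shares (renormalized).
- **Weights.** Log-normal with mean 1 and log-scale SD
  `weight_lognormal_sd` (default 0.5): positive, heterogeneous, with
  controllable spread; estimators must be scale-invariant anyway.
- **Activity layers.** Weekly participation is Bernoulli with
  `π_i = expit(x_i'b_part)`; conditional on participation, survey-day
  activity is Bernoulli with the per-person frequency `f_i = p_i/π_i`
  (clipped at 1 with a warning), which makes the marginal survey-day
  prevalence exactly `p_i = expit(x_i'b_prev)`.  Conditional on
  survey-day activity, daily travel activity `T̃` is log-normal with
  mean `x_i'b_int` (log MET-hr/day) and SD `σ₀` (default 0.8, a
  realistic residual spread for log activity data).  A uniform
  proportion of the MET-hours is assigned to walking (3 MET) and the
  rest to cycling (6 MET), so `3·walk_hours + 6·cycle_hours = T̃`
  exactly; no mode-split model is imposed beyond this.
- **Weekly trip counts.** Participants take `1 + Poisson(λ)` trips
  (default λ=2), split binomially between walking and cycling, which
  guarantees participants report ≥1 trip and non-participants report 0.
- **Missingness.** Independent per covariate field at `missing_rate`
  (default 0.005, matching the sub-percent item nonresponse of the
  surveys this emulates); the simplest mechanism that exercises the
  missing-data filter.

Coefficient maps are keyed `intercept`, `age` (per decade, centered at
40) and `variable:level`; unknown keys raise a configuration error
naming the term.  Default intercepts are calibrated so the implied
population-level rates look like a 2017-style metropolitan survey
(overall prevalence ≈0.20, participation ≈0.75, reference-profile
participation 0.65, reference frequency ≈0.16, reference weekly
intensity ≈2.6 MET-hr/week); subgroup effects follow the qualitative
pattern of such surveys (strong positive carlessness and density
effects, positive education/income gradients, lower activity among
Black, Asian and Hispanic profiles).

What the generator does **not** emulate: the surveys' sampling designs
(random-digit dialing vs address-based, state oversampling mechanics),
trip-level diary structure, informative missingness, within-household
behavioral correlation, and any inconsistency between diary-day
activity and weekly recall (the generator enforces consistency; real
respondents need not).  Passing tests therefore demonstrate that the
estimators recover a correctly specified generative truth — not that
the modelling assumptions hold in real survey data.

## Cohort filters

Applied in a fixed order: inclusive age window 19–65; metro > 1M flag;
removal of records missing any field needed for participation
estimation (weight, weekly trip counts, every regression covariate);
removal of all records from states with fewer than 150 distinct
households remaining; removal of records whose weekly travel activity
exceeds 50 MET-hr/week.  The weekly scale for the outlier rule is
`7·f·T̃` with `f` the sample-level prevalence/participation ratio of the
pre-outlier sample (the weekly dose definition is `T = 7fT̃` with a
sample-level `f`, so the filter needs a provisional one); a
`outlier_rule="unscaled"` switch applies the cruder `7·T̃`
extrapolation instead.  The first two filters are record-local and
commute; the state filter is not, and its position is fixed.  An
attrition report records counts at every step.

## Survey-weighted estimation

Weighted proportions use `Σwx/Σw` with a 95% Wald interval on the Kish
effective sample size `n_eff = (Σw)²/Σw²`, truncated to [0,1].  Wald
(not Wilson) is the simplest method consistent with large-sample survey
intervals; coverage is verified by simulation (93–97% at n=5,000 under
log-normal weights).  The association screen is a Pearson chi-square on
the weighted contingency table deflated by the mean design effect
`n_l/n_eff,l` of the level-wise estimates — a first-order correction in
the spirit of survey-design-adjusted chi-square tests, not a full
second-order Rao–Scott correction (the screen is qualitative here).

## Regression models

Prevalence and participation are logistic regressions on `I[T̃>0]` and
`I[nwalk+ncycle>0]`; intensity is a linear regression of `log T̃` among
active travelers.  Default terms: sex, age (continuous linear; the
surveys give no categorical coding), density, income, education, cars,
race, Hispanic status, race×Hispanic, state, state×season.  Fits are
complete-case per model and unweighted by default — the state terms
absorb state-level oversampling — with a `weighted` switch for
sensitivity.  Fitting is maximum likelihood via statsmodels
(GLM/OLS with patsy treatment coding); `σ₀` is the
degrees-of-freedom-corrected root mean square residual.

Subgroup parameters are model predictions at the reference profile
(White, non-Hispanic, male, California, fall, density 2,000–3,999,
income USD 35–50k, high-school education, two cars; age at the fitted
sample mean unless specified) with the subgroup's overrides applied.
Probabilities are the inverse logit of the linear predictor — a fitted
logistic probability, which necessarily lies in (0,1); the exponential
form sometimes written for these quantities is the odds and can exceed
one.  Parameters are invariant to the choice of reference levels
(verified to 1e-6).

## The comparative risk assessment

`σ*` is taken as the square root of the log-normal variance expression
`(e^{σ₀²}−1)e^{2μ+σ₀²}`, so that the weekly scaling `σ' = 7fσ*` acts on
a standard deviation.  Weekly mixtures are sampled by moment inversion:
`s² = ln(1+(σ'/μ')²)`, `m = ln μ' − s²/2`; a zero mean with positive SD
is rejected as un-matchable.  Baseline physical activity is sampled by
inverse-CDF interpolation of a quantile table (or a point mass for
analytic limits).  Quantiles use the midpoint probability grid
`(l−0.5)/m` with the inverted-CDF (order-statistic) definition — the
midpoint grid avoids 0th/100th-percentile instability, and the
order-statistic definition makes a sample evaluated on its own grid
reproduce its sorted values exactly.  The exposure-response curve is
linearly interpolated between knots and held constant beyond the last
knot; validation requires knots to start at (0, 1), strictly increasing
exposures, and non-increasing positive relative risks.

Subgroup and reference travel-activity vectors are drawn independently
(as the procedure simulates two separate vectors); each group's
substream is seeded from the run seed plus a hash of that group's
mixture parameters, so a subgroup identical to the reference receives
the identical vector and yields PAF exactly 0, while distinct subgroups
get effectively independent draws.  A common-random-numbers option
pairs the draws for variance reduction but is off by default.  Defaults
`n_sim = 10⁶` draws and `m = 10,000` quantiles give a PAF Monte-Carlo
SD below 0.002 for subgroup-table-scale inputs (verified across 20
seeds).  Report tables round half-up to 2 decimals at presentation time
only.

### Packaged fixtures

The default exposure-response knots and baseline physical-activity
quantile table (`src/hot_equity/data/*_synthetic.csv`) are constructed
synthetic stand-ins with the qualitative shape of cohort-derived
leisure-time physical-activity curves (steep early mortality benefit
flattening at high doses; ~25% inactive baseline with a long right
tail).  They are not estimates from any cohort; substantive analyses
should supply cohort-derived files through the documented CSV formats.
All PAF magnitudes computed with the packaged fixtures are therefore
illustrative.

## Problem sizes and numerical choices

Test and acceptance runs use synthetic populations of 2,000–60,000
households, 100 reduced-size replicate fits (≈4,000 persons each) for
coefficient recovery, ~10 replicate pipelines of ≈42,000 persons for
end-to-end recovery of a designed 2× travel-activity contrast, and the
full `n_sim = 10⁶`, `m = 10,000` for single CRA runs — sizes chosen so
the whole suite runs comfortably on one CPU while leaving Monte-Carlo
error well inside the asserted tolerances.  Recovery assertions are
phrased in standard errors (3 SE), not absolute tolerances, so they
scale with the chosen sizes.

## Known limitations

- PAF point estimates carry no uncertainty intervals (the method
  reports point estimates; regression and Monte-Carlo uncertainty are
  not propagated).
- All new travel activity is assumed additional physical activity with
  no substitution between domains.
- The baseline physical-activity distribution is assumed common to all
  subgroups, which is known to be optimistic — real activity
  distributions vary by the same covariates being contrasted.
- The design-effect chi-square is a first-order screen; its p-values
  are not exact under strong weight/cluster structure.
- The generator's ground-truth defaults are a calibrated emulation, not
  fitted survey estimates; analyses of real microdata should inject
  their own person table through the CSV interface.
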