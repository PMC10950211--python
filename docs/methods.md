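# Methods

## The mortality model

Deaths are counted inside a fixed observation window (six weeks from election
day; four weeks as a robustness variant) for each of six consecutive years.
Within municipality *m* and stratum *s* (ten-year age band × sex, 18 strata by
default), counts are Poisson with rate `N_mst · h_ms` in the five baseline
years and `N_ms,T · (h_ms + π_m · IFR_s)` in the epidemic year: the baseline
hazard `h_ms` is assumed constant across baseline years (window-matching
across calendar years removes seasonality), and the epidemic adds an excess
hazard equal to prevalence times the stratum infection fatality ratio. The
assumptions this inherits: infections are distributed through a municipality's
population independently of age and sex (prevalence is a single municipal
scalar), the IFR table is known and external, and deaths of the window are
attributable to infections present around the election.

**Estimation.** The estimator maximises the joint likelihood over
`(h_m1..h_mS, π_m)` subject to `π_m ∈ [0, 1]`, `h ≥ 0`. For fixed `π` the
partial maximiser of each `h_s` solves a quadratic (the stationarity condition
of a sum of two Poisson log-likelihood terms), so the profile likelihood in
`π` is evaluated in closed form per stratum and maximised by a bounded
one-dimensional search (tolerance 1e-10). For a single stratum the joint MLE
reduces analytically to `h = ΣD_base / ΣN_base` and
`π = max(0, (D_T/N_T − h)/IFR)`; the test suite holds the numeric path to that
closed form at 1e-6 over random instances.

Estimation is constrained maximum likelihood, not full Bayes: the likelihood
is isolated in `_profile_loglik` so a hierarchical backend could be added, and
an optional Gamma-Poisson empirical-Bayes shrinkage of the *baseline* hazards
toward national stratum hazards (`fit_baseline_hazard(pooling="shrink")`) is
available for the baseline-mortality covariate. `π` is constrained to [0, 1]
because prevalence is a proportion.

**Uncertainty.** Intervals are profile-likelihood sets at the χ²(1) cutoff
(3.84 for 95%), chosen over Wald intervals because `π̂` frequently sits on the
zero boundary where the Wald approximation fails. Estimates at 0 or 1 carry a
`boundary` flag.

**Population extrapolation.** Census counts observed through three years
before the election are extended per stratum by a linear or log-linear trend
(`auto` = log-linear when all observed counts are positive, else linear,
since the log trend is undefined at zero); strata with a single observed year
carry it forward with a warning; predictions are floored at zero.

**Transforms.** For regression use, prevalence point estimates are recoded as
decile or quintile ranks (1-based, near-equal bins, treated as continuous),
quartile categories, or `log(π̂ + δ)` with `δ` = half the smallest positive
estimate. Ties — abundant, since many municipalities sit at exactly zero —
are broken by stable municipality-id order.

## Exposure probability

`P(know ≥ 1 infected) = 1 − (1 − π)^k` under voter homogeneity. The default
`k = 15` is deliberately conservative (an inner circle, also absorbing the
fact that not every infection is noticed); `k = 150` is the Dunbar variant.
An optional symptomatic-fraction multiplier on `π` defaults to 1. Threshold
classification uses the point estimates `π̂`.

## Effect designs

All designs share one design matrix: logged census covariates (logs of
density, sex ratio, and the six shares; median income raw), 2014 turnout,
candidate count, the baseline-mortality covariate (population-weighted mean
fitted hazard — expected window deaths over population), the lagged incumbent
share, and county indicators. Rows with missing values are dropped with a
logged count; non-positive values entering a log are lifted by half the
column's smallest positive value, with a warning. Analysis is restricted to
municipalities whose incumbent runs again.

- **Lagged-DV OLS** (the workhorse): county fixed effects via explicit
  indicators (a within-county demeaned path exists and is held to the dummy
  path at 1e-8 by a Frisch–Waugh test). Standard errors are
  heteroskedasticity-robust (HC1) by default — the SE type is configurable
  since reasonable practice varies; clustering is applied where the design
  demands it (below).
- **Predicted margins** at chosen transform levels hold all other regressors
  at sample means (so county indicators at their shares); the top-vs-bottom
  contrast comes with a delta-method standard error.
- **First differences**: the 2020−2014 change regressed on the same design
  minus the lag.
- **Difference-in-differences**: treated = top two quartiles of the spread
  measure (computed on the estimation sample; ties by stable id order). The
  naive four-cell contrast and the two-way (municipality + period)
  fixed-effects regression coincide exactly without covariates — an identity
  the tests enforce at 1e-10; covariate *changes* may enter interacted with
  the post period. Inference clusters on municipality.
- **Propensity-score matching**: logistic regression of treatment on the full
  control set (including the lagged share), then greedy 1:1 nearest-neighbour
  matching without replacement, treated processed in descending score order,
  seeded tie-breaks, pairs discarded beyond a 0.025 caliper; the workhorse
  model is refit on the matched sample. Balance is reported as standardized
  mean differences.
- **Placebo**: the workhorse design with the 2014 outcome, the 2008 lag, and
  the unchanged 2020-based exposure; under correct specification its
  coefficient is null. Small sub-panels trigger a warning
  (threshold configurable).
- **Parallel trends**: the 2008→2014 change contrasted between treatment
  groups, plus group-by-year means for plotting.
- **Interactions**: spread × moderator terms added to the workhorse model.
  The anxiety moderator is a two-item additive index (responses mapped to
  {0, 1/3, 2/3, 1}, averaged per respondent, then averaged within county ×
  municipality-size cells) merged by county × size, with errors clustered on
  those cells; welfare moderators are the raw 2014→2017 changes in median
  income and unemployment share (raw rather than relative change — a
  documented choice, as either is defensible). Marginal effects are evaluated
  at 20 evenly spaced moderator values, other covariates at means.

## The synthetic world

The generator emulates the *structure* of a municipal election hit by an
early epidemic, not any particular country's geography:

- **Populations.** Log-normal municipality sizes (median 150,000, σ_log 0.6,
  floored above the 1,000-inhabitant inclusion rule), Dirichlet age structures
  tilted older in less urban places, near-balanced sexes, linear growth.
  The city-scale default is deliberate: it keeps six-week mortality counts
  informative about prevalence, which is what makes desk-scale validation of
  the estimator possible (see *Limitations*).
- **Prevalence field.** Zero-inflated Beta: 40% exact zeros in expectation,
  `Beta(1.2, 30)` tail (scaled by a configurable maximum), with the
  probability of being untouched falling with urbanicity (epidemics reach
  cities first) — this is also the planted confounding that the matching
  tests rely on. An optional within-county shock correlates the field
  spatially; no default claim is made for its strength.
- **Mortality.** A Gompertz-like synthetic annual schedule by age and sex
  times a log-normal municipal frailty; window hazards scale by window length.
  Six-week baseline and excess deaths are drawn as separate Poisson counts;
  the four-week window is a *binomial thinning* of the same draws (baseline
  kept with probability 4/6, excess with 0.75, reflecting death delays) so
  the two windows are coherent, as they are in reality, rather than
  independent.
- **Elections.** 2008/2014/2020 incumbent shares share covariate and county
  structure; the planted effect `β` (default 2.5/9 pp per decile step, i.e. a
  2.5 pp decile-1→10 span) enters only the 2020 equation unless a leak or a
  differential pre-trend is explicitly planted. Shares are truncated to
  [0, 100] after noise; the pre-period elections carry their own noise term
  so a noiseless 2020 equation still has a non-collinear lag. Incumbents run
  in 56% of municipalities; affiliations left/right/other at 22/47/31;
  turnout ~ N(63.5, 8) clipped.
- **Survey cells.** County × size-quintile cells with ~16 respondents each;
  cell anxiety lives in [0, 1] and tracks cell-mean prevalence with a
  configurable strength (0 severs the link). A 2008-share subsample fraction
  (default 0.3) stands in for the real-world attrition of traceable
  incumbents across electoral reforms.

Everything derives from one root seed through fixed per-stage streams;
identical `(config, seed)` gives byte-identical tables.

## Numerical choices

- Profile search: bounded Brent, `xatol = 1e-10`; interval roots by `brentq`;
  explicit boundary snap when the likelihood is maximised at 0 or 1.
- Municipalities with zero epidemic-year population are excluded (logged), as
  are strata with zero baseline exposure.
- Rank bins: stable sort by (value, id); bin sizes differ by at most one;
  degenerate all-equal inputs raise rather than returning arbitrary ranks.
- Singular design matrices raise an error naming the collinear columns.
- Matching is O(T·C) greedy; with equal gaps the control is drawn with the
  run's seed, making matches reproducible byte-for-byte.

## What the tests do and do not show

The suite demonstrates that, on data generated *by this model*, the estimator
recovers the prevalence field (slope of estimate on truth within [0.9, 1.1],
95% profile intervals covering 90–98% of non-boundary truths), the designs
recover a planted effect without size distortion (type-I error within
[0.03, 0.07] at nominal 0.05), the placebo is null when the effect exists
only in 2020, and the matching contract holds exactly. It does **not** show
that real mortality records satisfy the model: reporting delays, seasonal
misalignment, hospital-saturation mortality, care-home clustering, and IFR
misspecification are all absent from the generator by design.

## Limitations

- **Small municipalities.** The π ≥ 0 boundary inflates near-zero estimates
  when the per-municipality death signal is weak; at village or small-town
  scale (thousands of inhabitants) this attenuates the recovery slope well
  below 1 even though intervals stay calibrated. This is intrinsic to
  excess-mortality prevalence estimation at fine resolution — and is exactly
  why downstream regressions use rank transforms rather than raw `π̂`. The
  generator's city-scale default sidesteps it for validation; users applying
  the model to small units should expect noisy, boundary-heavy estimates.
- Rank transforms computed from `π̂` inherit its measurement error; decile
  misclassification attenuates the per-decile coefficient slightly toward
  zero relative to ranks of true prevalence.
- The joint MLE has a small negative finite-sample bias at high prevalence
  (epidemic-year deaths leak into the jointly fitted baseline hazards); it
  vanishes as counts grow.
- The exposure model assumes homogeneous, independent contacts — no household
  or network structure.
- No turnout modelling, no spatial standard errors, no multiple-testing
  correction across designs.
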