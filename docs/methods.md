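# Methods

`ttemu` implements a target-trial emulation for a new-user, active-comparator
drug question on administrative claims: does initiating metformin within six
months of an advanced prostate-cancer diagnosis, among men starting
androgen-deprivation therapy (ADT), change all-cause or cancer-specific
mortality over three years?  Because the motivating registry–claims linkage
cannot be redistributed, the package pairs the full analysis pipeline with a
synthetic claims generator whose causal structure is known, so every stage is
validated against ground truth.

## Design

**Eligibility and time zero.**  Patients qualify if they are ≥ 66 years old
at diagnosis, diagnosed 2008–2019, start ADT (hormonal fill or orchiectomy)
within 183 days of diagnosis, have no metformin fill in the 183 days before
diagnosis (with continuous Part D drug coverage over that window), no
metformin contraindication in the prior year, continuous Parts A/B coverage
without an HMO span over the prior 365 days, and are alive with Part D
coverage through day 183 after diagnosis.  Excluded patients are attributed
to the first failed criterion in that order, so the attrition flow sums to
the population.  Time zero is the ADT start date for non-initiators and
max(ADT start, first metformin fill) for initiators; follow-up ends at the
earliest of death, disenrollment, 1095 days after diagnosis, or the
administrative end of study (2020-12-31).

Calendar conventions: "6 months" = 183 days, "1 year" = 365 days, "3 years"
= 1095 days, closed intervals; follow-up months are 30-day bins from time
zero.  Continuous enrollment requires the window endpoints covered and
tolerates interior gaps ≤ 31 days.

The eligibility list names chronic heart failure among metformin
contraindications, but the eligible population it describes retains
prevalent CHF as a baseline covariate; the package therefore excludes at
screening only on hepatic failure, severe renal disease, and metabolic
acidosis (configurable), while *new-onset* CHF during follow-up counts as a
contraindication that exempts a subsequent discontinuation.

**Exposure.**  A day is on-drug iff it lies within `[fill_date, fill_date +
days_supply − 1]` of some fill (union of intervals; early refills do not
stockpile).  Discontinuation occurs at the first uncovered run inside the
observation window longer than the gap allowance (30 days primary, 60 days
sensitivity), dated to `run_start + gap_days`.  Initiators deviate from
protocol at a discontinuation not preceded by a contraindication diagnosis;
non-initiators deviate at a metformin fill after the 6-month classification
window not preceded by a diabetes diagnosis (the indication).  Whether the
source design dates discontinuation at gap start or gap completion is
unstated; the gap-completion convention here is declared, not inferred.

**Estimators.**  The intention-to-treat analog is a weighted Cox model
(Efron ties, robust sandwich SE) of time from time zero, with stabilized
inverse-probability-of-treatment weights (numerator: marginal initiation
probability; denominator: logistic model on the baseline adjustment set —
age, race/ethnicity, marital status, education quartile, Charlson category,
diabetes, CHF, cerebrovascular disease, hypertension, depression, PCP-visit
count) and the same covariates in the outcome model.  The per-protocol
analog censors person-months at deviation and fits a weighted pooled
logistic model of monthly death on strategy, the baseline set, and month +
month², with SEs from a sandwich clustered on patient; under rare monthly
events the exponentiated strategy coefficient is the hazard-ratio analog.
Adherence and loss-to-follow-up weights are stabilized cumulative-ratio
weights fit separately by strategy (numerator: baseline covariates + month
terms; denominator adds the time-varying covariates).  All weights are
truncated at the 99th percentile (linear-interpolation quantile), adherence
and LTFU weights each truncated before multiplication.  Cancer-specific
mortality uses the cause-specific hazard convention: other-cause deaths
censor at the death month.  Confidence intervals are 95% normal on the
log scale.

## Discrete-time conventions that matter

These choices were forced by validation against the generator's known
truth; each removes a specific artifact of naive person-month analysis.

* **Delayed entry.**  Eligibility guarantees survival through day dx+183
  while time zero is earlier, which creates immortal person-time whose
  length differs between arms (initiators fix time zero later).  The Cox
  fit uses left truncation at dx+183; the pooled logistic excludes months
  overlapping the guarantee window from the hazard fit (they remain in the
  censoring-weight models).  Without this the null scenario shows a
  +0.10 log-HR artifact.
* **Complete risk months only.**  A final month cut short by the
  administrative boundary is an incomplete Bernoulli trial and is excluded
  from the hazard fit.
* **Censoring at month end.**  A deviator's detection month stays in the
  risk set (event-free if survived), so that month contributes deaths and
  survivor time symmetrically; with death-beats-censoring priority alone
  the detection month would enter the fit only for those who died in it.
  Consistently, the cumulative censoring weight for month m multiplies the
  monthly uncensored-probability ratios of months strictly before m
  (covariates and censoring risk are assessed at month start, censoring
  takes effect at month end).
* Within-month terminating-cause priority is death > deviation > LTFU >
  administrative end.

## The synthetic claims generator

One dataset is produced from a seed and a declared configuration; every
stochastic component draws from a named substream in patient-major order,
so identical configurations are byte-identical and appending patients never
perturbs earlier ones.

Defaults emulate the study conditions: diagnoses uniform over 2008–2019,
age truncated normal 75.4 (SD 6.8, ≥ 66), ADT 0–60 days and first metformin
fill 0–150 days after diagnosis, ~1.5% initiation driven chiefly by
baseline diabetes (prevalence 10.6%, initiation log-odds +2.0), baseline
monthly all-cause hazard 0.015 (≈ 42% three-year mortality), 63% of deaths
cancer-specific, monthly discontinuation 5%, monthly disenrollment 0.2%,
30-day supplies with uniform 0–10-day refill delays, and ~13% of patients
planted with exactly one eligibility violation.  Death is a monthly
logistic hazard: logit p = logit(h₀) + log(HR)·on_treat(m) + Σ γⱼ Lⱼ(m).
Death cause is a mixture whose cancer share is scaled by
`true_hr_pca / true_hr_allcause` for on-treatment deaths, so both
cause-specific hazard ratios are configurable.

The generating exposure period coincides with the protocol's definition of
continuous use: the drug effect persists through the allowed refill gap
(30 days past the last supply end), so the per-protocol pooled-logistic
estimand equals the generating hazard ratio by construction.  The final
partial follow-up month draws a death with full-month hazard and discards
it if it falls beyond the window; the analysis-side exclusion of partial
months makes this immaterial.

What the generator does **not** emulate: real NDC/ICD/CPT coding (toy event
codes stand in), dose and formulation, Medicare Advantage logic, geographic
SES linkage, calendar-period effects, correlated comorbidity onset, or
frailty beyond the measured covariates.  Passing tests therefore show the
pipeline's statistical machinery is correct under the declared generative
assumptions — not that any real-data finding is correct.

## Validation scenarios and study sizes

Two canonical scenarios (module `ttemu.studies`), with parameters chosen
once as realistic estimator-validation conditions:

* **Null ITT** — true HR 1, confounding by diabetes only (prevalence 0.30,
  initiation log-odds +1.5, death log-hazard +0.7), ~30% initiation, ADT
  within 7 days and first fill within 14 days of diagnosis so both arms
  share the diagnosis anchor (otherwise the survive-6-months condition
  removes different immortal time per arm).  200 replicates of n = 5000.
  The weighted analysis is doubly adjusted (IPW plus the scenario's
  measured covariates in the Cox model), mirroring the pipeline's ITT
  estimator; its measured calibration at these sizes is mean robust SE /
  empirical SD ≈ 1.00, i.e. essentially nominal CIs.
* **Effect recovery** — conditional on-treatment HR 0.7, the same
  confounding, and informative discontinuation: diabetics (who have the
  indication) adhere, non-diabetics stop (monthly base 4%, log-odds −1.5
  per current diabetes), with diabetes onset 1%/month making the censoring
  depend on a post-baseline covariate.  Indicated initiation in the
  non-initiator arm is disabled: it is protocol-compliant treatment
  crossover, so with it the strategy estimand differs from the generating
  on-treatment HR by construction (≈ +0.035 log-HR dilution at these
  rates).  200 replicates of n = 2000 (the reduced replicate size keeps the
  full-pipeline study tractable; the Monte-Carlo standard error of the mean
  log HR is ≈ 0.01).

At n = 2000 with ~25 outcome-model parameters and ~600 events per
replicate, the pooled-logistic MLE carries a small finite-sample bias away
from zero (≈ −0.02 log-HR, shrinking with n); it is visible in the
no-censoring variant of the recovery scenario and is documented rather than
corrected.

## Degenerate inputs and numerical choices

Zero-patient configurations produce empty, schema-valid tables.  A
censoring-weight stratum with no censoring events yields unit weights with
a degeneracy note instead of a failed fit.  Single-strategy cohorts, zero
events in a stratum, separation, and non-convergence raise a typed
estimation error carrying diagnostics.  Design matrices drop exactly
aliased columns (R/SAS-style aliasing) — the toy comorbidity score can be
an exact combination of the individual condition indicators — and the
comorbidity score enters adjustment models numerically, since its sparse
top categories can quasi-separate small cohorts.  Logistic fits run on an
in-package damped-Newton solver working off the k×k normal equations
(person-month tables reach hundreds of thousands of rows; a general GLM
implementation that refactorizes the full design each iteration needs
minutes and gigabytes there), with coefficients asserted against a
reference GLM implementation to 1e-8 in the test suite; a sparse-event
censoring model that quasi-separates is refit with a weakly informative L2
stabilizer, recorded in the weight diagnostics.  The pooled-logistic
sandwich is the clustered score outer product between bread inverses.
Percentile truncation uses the linear-interpolation empirical quantile.
The weight-scale invariance of point estimates (not SEs) is a tested
property.

## Known limitations

Weight-model estimation error is not propagated into confidence intervals
(robust SEs treat weights as known — conservative for the ITT weights).
The per-protocol estimand includes protocol-sanctioned off-treatment time
(after a contraindication develops, or indicated initiation in the
non-initiator arm), so it equals the generating on-treatment hazard ratio
only when those pathways are rare; the recovery scenario keeps them small.
The 60-day sensitivity analysis reuses the 30-day generator conventions.
Zip-code SES, staging subgroups, and competing-risks (subdistribution)
models are out of scope.
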