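# Methods

This note documents the statistical model behind `statindisparity`, the
assumptions baked into the synthetic cohort generator, and the design
choices made where the problem was genuinely open.  It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Cohort definitions

The unit of analysis is the patient.  Study entry is the later of the CAD
diagnosis date and the first primary-care note inside the study window
(2000-01-01 to 2011-12-31 by default); exit is the last primary-care note
in the window.  Eligibility requires primary-care notes on at least two
distinct dates, at least 365 days between entry and exit (inclusive:
exactly 365 days qualifies), and non-missing sex and median income.
Excluded rows carry one reason each, with precedence missing demographics
→ too few notes → insufficient follow-up.

*Statin use* is ≥ 1 start/renew prescription action dated within
[entry, exit].  *Persistence* requires a start/renew within the final 365
days of follow-up with no explicit discontinuation on or after that
record's date.  All durations are whole calendar days ("a year" and
"twelve months" both mean 365 days; no month arithmetic), and a renew and
discontinue on the same date resolve as discontinued — the conservative
reading.  Smoking status and baseline BMI come from the latest record
strictly before entry; maximum LDL-C is the highest value strictly before
exit; cardiology evaluation is any cardiology note within the study
window.  For diagnosis-type variables (diabetes, CABG, MI, family
history), absence of a record means absence of the diagnosis, since
absence is not affirmatively recorded in EMR data.

Age groups for standardization are [18,45), [45,55), [55,65), [65,75),
[75,85), 85+.  The source analysis standardizes on "age group" without
stating the bins; decade bins with an explicit 75+ split are the declared
choice, and continuous covariates never enter standardization unbinned.

## Standardization and the disparity decomposition

For event probabilities `P_m`, `P_w` and strata `s` of the selected
covariates, the adjusted probability for women re-weights women's
stratum-specific rates by men's stratum distribution,
`P_w_adj = Σ_s w_m(s) r_w(s)`, giving

    D_obs = P_m − P_w,   D_adj = P_m − P_w_adj,
    explained = D_obs − D_adj,   fraction = explained / D_obs.

`explained` is computed exactly as that difference, and `fraction` is
reported as undefined (not a substituted number) when `D_obs = 0`.
`P_w_adj` is a convex combination of women's stratum rates, hence always a
proper probability.

**Degenerate strata.** A stratum with positive men's weight but no women
has no defined `r_w`.  Such strata are dropped from the reference
distribution, the remaining men's weights renormalized, and the dropped
strata listed in the result — silently extrapolating a rate would have no
empirical basis, and renormalization keeps `P_w_adj` a probability.

**Two-level standardization.** Reported adverse reactions exist only for
statin users, so they cannot enter a whole-cohort stratification.  Within
each stratum of the everybody-covariates, women's rate among users is
first re-weighted to men's distribution of the users-only covariates in
that same stratum; the resulting stratum rates then combine with men's
first-level weights.  Persistence is reported on two bases, labelled in
every output: among statin users, and against the whole cohort via the
composition P(persistent) = P(initiate) × P(persist | initiate), in which
the users-only covariates adjust only the persistence factor.  The
whole-cohort base is the default for contribution summaries because the
disparity among users alone is near zero (women who initiate persist
about as well as men), which makes user-base fractions numerically
unstable.

**Sensitivity sets.** CAD-severity markers (CABG, MI) can be added to any
standardization set as ordinary joint covariates; the race = "Other"
exclusion is a row filter ahead of the same computation.

## Uncertainty

Variances and 95% intervals come from a percentile bootstrap stratified by
sex: each replicate resamples patients with replacement within men and
within women, preserving each sex's count, and recomputes the entire
standardization — stratum weights included.  Defaults: 1,000 replicates in
the library, smaller in the pipeline demo.  Replicates with `D_obs = 0`
are counted and excluded.  Patients are the resampling unit; resampling
whole provider clusters (within sex) is available as an option but off by
default, since the reference procedure stratifies by sex only.  Under a
provider random effect the patient-level bootstrap is mildly
anticonservative; the calibration experiment below therefore uses
independent patients.  Imputation is not re-run inside replicates
(replicates use a completed dataset), a documented simplification.

## Regression

Logistic models for initiation (all patients) and persistence (users) use
maximum likelihood via IRLS (gradient tolerance 1e-8, ≤ 100 iterations,
through statsmodels GLM).  Clustering within primary-care providers is
handled GEE-style with independence working correlation: point estimates
are the ML estimates and the covariance is the sandwich with scores summed
within provider.  No finite-sample scaling is applied to the sandwich, so
with singleton clusters it reduces exactly to the HC0 estimator.
Reference levels: male sex, White race, non-government insurance, youngest
age group; income enters per $1,000, LDL per 10 mg/dL, age per year.  A
fit with any |coefficient| > 20 is flagged non-converged (separation).
Wald p-values from the robust covariance are Simes–Hochberg-adjusted
within each model's non-intercept coefficients (the multiplicity family is
otherwise unspecified in the source procedure).

## Multiple imputation

Smoking, maximum LDL-C and baseline BMI are imputed by chained equations:
a Bayesian logistic draw for smoking and normal linear draws (coefficients
and residual variance drawn from their approximate posteriors) for LDL and
BMI, conditioning on sex, age, diabetes, cardiology evaluation, both
outcomes and the other two imputed variables, cycled 10 times; m = 20
datasets by default (m = 5 in the pipeline demo).  Coefficients are pooled
on the log-odds scale and disparity fractions on the raw scale by Rubin's
rules, T = W + (1 + 1/m)B with the standard small-sample degrees of
freedom.  Whether the reference analysis pooled its decomposition across
imputations is unstated; pooling is this package's recorded assumption.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes, with defaults
calibrated to the reference cohort's published per-sex marginals:

| parameter | default (men / women) | units |
|---|---|---|
| cohort size, female share | 24,338; 0.37 | patients |
| age at entry, truncated normal on [18, 100] | 68.4 (11.8) / 72.9 (12.1) | years |
| ever-smoker prevalence | 65.6 / 49.8 | % |
| cardiology evaluation | 64.5 / 57.5 | % |
| diabetes; family history of CAD | 41.9 / 40.7; 14.9 / 15.1 | % |
| adverse reaction among users | 21.7 / 27.1 | % |
| missingness: smoking / LDL / BMI | 8.4 / 9.0 / 14.4 | % |
| providers; random-effect SD | 200; 0.3 | log-odds |

Initiation and persistence are drawn from logistic models on sex, age
group and the binary covariates, plus a provider-level normal intercept
shared by both outcomes (the clustering the GEE adjustment targets).
Slopes echo the published odds ratios; intercepts were solved by
enumeration so that men's marginal initiation is 87.7% and persistence
among male users 81.3%.  Covariates are drawn independently within sex —
the joint distribution of the source population is unknown, so
independence is a declared simplification, not an assertion about the
study data.  Missingness is missing-at-random given sex and age (an
exponential tilt in age with a female offset, normalized to preserve the
marginal rate); the mechanism is unstated in the source, and MAR keeps the
truth recoverable while exercising the imputation non-trivially.

Event histories are constructed so the cohort builder's derived
classifications reproduce the drawn outcomes exactly: persistent users get
a renewal within 12 months of exit and no later discontinuation;
non-persistent initiators lapse (last record > 12 months before exit) or
explicitly discontinue, 50/50, covering both classifier failure modes.
Ages are truncated to [18, 100] (adult cohort).

What the generator does **not** emulate: covariate dependence beyond sex,
informative missingness, time-varying covariates, provider effects that
differ between the two outcomes, or free-text adverse-reaction
documentation (adverse reactions are generated directly as flags).
Passing recovery tests therefore demonstrate correctness of the
estimators under these stated conditions, not fidelity to any real EMR
population.

## The enumeration oracle

`generate_true_decomposition` computes the exact population-level
decomposition for any configuration by enumerating the finite stratum grid
(6 age groups × the binary covariates) and integrating the provider random
effect with 61-node Gauss–Hermite quadrature; persistence among users uses
the exact conditional P(persist | initiate) including the correlation both
outcomes inherit from the shared provider effect.  No sampling is
involved, so it is an independent target for the empirical estimators.

## Validation experiments and problem sizes

* **Full mediation** (n = 50,000): no direct sex coefficient and identical
  non-standardized covariate distributions; the joint explained fraction
  must lie within 4 bootstrap SE of 100%.
* **No mediation** (n = 50,000): identical covariate distributions, direct
  sex effect only; every fraction within 4 bootstrap SE of 0.
* **Oracle convergence** (n = 200,000): sampled fractions within 2
  percentage points of the enumeration truth.  The experiment uses a
  configuration with a pronounced initiation disparity and no missingness:
  a variance analysis showed the default configuration's joint-fraction
  Monte Carlo SD (≈ 1.8 points at this n) would be comparable to the
  tolerance, whereas the pronounced-disparity configuration keeps it near
  0.8 points; and the enumeration describes complete data.
* **Bootstrap calibration** (200 cohorts × n = 6,000, 200 replicates
  each): the 95% percentile interval covers the enumeration truth of the
  joint initiation fraction in 90–99% of cohorts.  Patients are generated
  independently (provider SD 0, no missingness) because that is the regime
  in which the patient-level bootstrap targets the estimator's true
  sampling distribution.

Sizes were chosen so the full suite and the acceptance script each run in
a few minutes on one CPU while leaving the checks statistically sharp.

## Known limitations

* Fractions are ratios with a small-difference denominator; they are
  noisy, can exceed 100% or be negative in samples, and their bootstrap
  intervals are wide.  Reports carry the observed disparity alongside.
* With provider clustering, patient-level bootstrap intervals are mildly
  narrow; the cluster-resampling option trades that for replicate-size
  variability.
* Marginal (population-averaged) logistic coefficients recovered from
  cohorts with a provider random effect are attenuated by ≈ 1.5% at the
  default SD relative to the conditional generating values — well inside
  the recovery tolerances, but visible at extreme random-effect scales.
* The two-level "all patients" base treats initiation as unadjusted by
  users-only covariates; that is the only coherent composition, but it
  means adverse-reaction contributions are defined through persistence
  only.
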