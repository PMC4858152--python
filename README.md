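# statindisparity

Decomposition of the sex disparity in statin therapy among patients with
coronary artery disease (CAD), as a tested, reusable pipeline.

Women with CAD are less likely than men to start statin therapy and to
remain on it.  Given a longitudinal primary-care cohort, this package
quantifies how much of that gap is attributable to measurable differences
between the sexes — age structure, smoking history, cardiology referral,
and reported adverse reactions to statins — using *direct standardization*:
women's covariate distribution is re-weighted to men's, and the shrinkage
of the gap under that counterfactual is the part the covariates explain.

Because the underlying electronic-medical-record data are institutional and
not shareable, the package ships a synthetic cohort generator with the same
statistical structure (sex-differential covariate distributions, logistic
outcome models, provider-level clustering, missing data) and an exact
enumeration oracle, so that every stage — cohort construction, multiple
imputation, cluster-robust regression, standardization, bootstrap — is
testable end to end.

## The estimands

For a binary event *E* (statin initiation, or persistent therapy) with
observed probabilities `P_m` (men) and `P_w` (women), and strata *s* of the
chosen covariates:

```
P_w_adj   = Σ_s w_m(s) · r_w(s)          w_m: men's stratum shares
D_obs     = P_m − P_w                    r_w: women's stratum event rates
D_adj     = P_m − P_w_adj
explained = D_obs − D_adj
fraction  = explained / D_obs
```

Covariates defined only for statin users (reported adverse reactions) enter
by **two-level standardization**: within each stratum of the
everybody-covariates, women's event rate is first re-weighted to men's
distribution of the users-only covariates, and the resulting rates are then
combined with men's first-level weights.  Uncertainty comes from a
sex-stratified bootstrap that recomputes the whole standardization on each
replicate.

Supporting stages follow standard epidemiological practice: multivariable
logistic regression with a provider-clustered sandwich covariance (GEE with
independence working correlation), Simes–Hochberg multiplicity adjustment,
and chained-equations multiple imputation with Rubin's rules for the three
incompletely observed covariates (smoking history, maximum LDL-C, baseline
BMI).

## Worked example

```python
from statindisparity import (CohortConfig, generate_analysis_frame,
                             decomposition_suite, stratified_bootstrap,
                             fraction_statistic)
from statindisparity.standardization import default_plan

frame = generate_analysis_frame(CohortConfig(n_patients=20_000, seed=12345))
suite = decomposition_suite(frame)
print(suite[["set", "p_m", "p_w", "p_w_adj", "fraction_pct"]])
```

On the default calibration this prints (abridged):

```
                                  set    p_m    p_w  p_w_adj  fraction_pct
                        use:age_group 0.8766 0.8221   0.8366          26.5
                      use:ever_smoker 0.8799 0.8255   0.8301           8.5
             use:cardiology_evaluated 0.8766 0.8221   0.8314          16.9
                            use:joint 0.8799 0.8255   0.8524          49.4
           persistence[all]:age_group 0.7096 0.6684   0.6877          46.8
    persistence[all]:adverse_reaction 0.7096 0.6684   0.6704           4.8
               persistence[all]:joint 0.7131 0.6748   0.7093          89.9
```

Reading the last row: men's persistence probability is 71.3%, women's
67.5%; re-weighting women to men's joint distribution of age group,
smoking, cardiology evaluation and (among users) adverse reactions moves
women's probability to 70.9%, so the four covariates jointly account for
89.9% of the observed gap.  A sex-stratified bootstrap supplies the
uncertainty:

```python
task = [t for t in default_plan() if t.name == "persistence[all]:joint"][0]
res = stratified_bootstrap(frame, fraction_statistic(task),
                           n_boot=500, seed=7, name=task.name)
# fraction = 89.9%  (95% CI 53.5 to 149.5, 500 replicates)
```

The wide interval is typical: explained fractions are ratios whose
denominator, the observed disparity, is itself a small difference of
probabilities.

A command-line pipeline wraps the same stages
(`statin-disparity run-all --out results/`), writing the cohort CSV files,
analysis rows, exclusion tallies, imputations, model tables, the
decomposition table and a run manifest; reruns with the same configuration
are byte-identical.

## Layout

- `src/statindisparity/synthetic.py`, `oracle.py` — cohort generator and
  exact enumeration truth
- `cohort.py` — entry/exit dates, eligibility, outcome and covariate
  derivation
- `imputation.py` — chained equations and Rubin pooling
- `regression.py` — logistic fits, clustered sandwich, Simes–Hochberg
- `standardization.py` — direct and two-level standardization (the core)
- `bootstrap.py` — sex-stratified bootstrap
- `report.py`, `cli.py` — summary tables and the pipeline driver
- `docs/methods.md` — the model, its assumptions, and design choices
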