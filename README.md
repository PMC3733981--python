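# trialsim

Monte-Carlo simulation toolkit for a recurring design question in two-arm
randomised controlled trials: when several binary prognostic factors are
balanced in the randomisation (stratified permuted blocks, minimisation),
must the analysis account for every *stratum* formed by their combinations,
or is adjusting for the factors' main effects enough — and among the common
adjustment methods, which keeps the type-I error rate nominal without
losing power?

It is written for trial statisticians and methodologists who want to
re-run, extend, or stress-test this comparison: sequential covariate-
adaptive randomisation, synthetic trial-data generation for continuous,
binary and time-to-event outcomes with interacting prognostic factors,
five treatment-effect estimators with uniform Wald inference, and a
replication engine that estimates type-I error, power and convergence
rates with common random numbers.

## The model

Outcomes are generated from a linear predictor with two-way interactions,

    η_i = α + β_treat X_treat,i + Σ_c β_c X_ic + Σ_{c<d} β_cd X_ic X_id,

as Y = η + ε (ε ~ N(0, σ²)) for continuous outcomes, via the
latent-logistic threshold Y = 1{η + ε > 0} for binary outcomes, and by
inverse-cumulative-hazard inversion T = H₀⁻¹(−ln U · e^(−η)) (exact
proportional hazards, exponential baseline, administrative censoring
calibrated to a stated control-arm event rate) for survival outcomes.
Correlated binary covariates come from thresholding a latent Gaussian
whose pairwise correlations are solved so that every marginal and joint
prevalence matches its target exactly. Three ready-made parameterisations
ship as fixtures — `mist2` (continuous), `augib` (binary), `pbc`
(survival) — each a table of prevalences and effect sizes (coefficients,
odds ratios or hazard ratios).

The five estimators, each returning the treatment effect on its link
scale (mean difference / log-OR / log-HR) with a Wald SE and p-value:

| method | idea |
|---|---|
| `covariate_adjusted` | regression on treatment + main effects |
| `stratified_fixed` | regression on treatment + stratum indicators |
| `stratified_random` | normal random intercept per stratum (REML / adaptive Gauss–Hermite / log-normal-frailty Cox) |
| `mantel_haenszel` | pooled OR with Robins–Breslow–Greenland variance (binary) |
| `stratified_cox` | Cox with stratum-specific baseline hazards (survival) |

See `docs/methods.md` for the full model account, calibration procedures
and numerical choices.

## Worked example

Simulate one survival trial from the `pbc` parameterisation (four binary
prognostic factors, censoring calibrated to a 40.4% control-arm event
rate), randomise 200 patients by minimisation, and fit the stratified
random-effects (frailty) analysis:

```python
import numpy as np
import trialsim as ts

fixture = ts.load_fixture("pbc")
model = fixture.covariate_model()
effects = ts.calibrate_intercept(fixture.effect_spec(beta_treat=-0.5),
                                 model, 0.404, seed=7)
rng = np.random.default_rng(7)
X, strata = ts.sample_covariates(model, 200, rng)
arm = ts.allocate_minimisation(X, rng, assign_prob=0.8)
time, event = ts.gen_survival(ts.linear_predictor(effects, X, arm),
                              effects, rng)
frame = ts.TrialFrame(X=X, arm=arm, family="survival", time=time,
                      event=event, stratum=strata, names=model.names)
result = ts.TrialModel(frame, method="stratified_random").fit()
print(result.summary())
```

```
Treatment effect (stratified_random, survival)
==============================================
  scale         log hazard ratio
  n             200
  estimate      -0.77902
  std. error    0.278929
  95% CI        [-1.32571, -0.23233]
  p-value       0.005224
  converged     True
  stratum var.  1.65955
  hazard ratio  0.458856
```

The generating treatment effect was a log hazard ratio of −0.5; this
realisation estimates −0.78 (hazard ratio 0.46) with an estimated stratum
variance of 1.66 on the log-hazard scale, and rejects the null at the 5%
level. A full comparison repeats this thousands of times per
(randomisation × analysis) cell:

```python
summaries = ts.run_dataset_type1("pbc", (100,),
                                 ("stratified_cox", "stratified_fixed"),
                                 n_reps=2000, master_seed=1)
print(ts.summarise_results(summaries))
```

which reproduces the characteristic small-sample contrast: the stratum-
indicator (fixed-effects) Cox fit inflates the type-I error at n=100
while the stratified Cox model stays nominal.

There is also a CLI: `trialsim run --scenario cfg.yaml --reps 5000
--seed 1 --out results.csv`, plus `trialsim grids` (the two-factor
interaction sweeps), `trialsim sensitivity --dataset mist2`, and
`trialsim calibrate --dataset pbc --n-patients 200`.

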