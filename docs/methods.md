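# Methods

`trialsim` is a Monte-Carlo laboratory for one design question in two-arm
randomised trials: when several binary prognostic factors are used in the
randomisation, does the analysis need to account for every *stratum* (each
combination of the factors), or is adjusting for the factors' main effects
enough — and which of the available adjustment methods keeps the type-I
error rate at its nominal level without giving up power?

## Data-generating model

Patients carry C binary prognostic factors X₁…X_C. Outcomes are generated
from a linear predictor with main effects and all two-way interactions:

    η_i = α + β_treat·X_treat,i + Σ_c β_c·X_ic + Σ_{c<d} β_cd·X_ic·X_id

- **Continuous**: Y = η + ε, ε ~ N(0, σ²).
- **Binary**: latent Y* = η + ε with standard-logistic ε; Y = 1{Y* > 0}
  (equivalently Y ~ Bernoulli(logit⁻¹(η)); coefficients are log odds
  ratios).
- **Time-to-event**: inverse-cumulative-hazard inversion
  T = H₀⁻¹(−ln U · e^(−η)) with U ~ Uniform(0,1), which yields exact
  proportional hazards for any baseline H₀; coefficients are log hazard
  ratios. We take an exponential baseline H₀(t) = λt with λ = 1 — only the
  event/censoring proportions matter for the comparisons, and those are
  controlled by the administrative censoring cut-point (below).

Higher-order interactions are never generated; stratified analyses
nevertheless adjust for whole strata, i.e. implicitly for all interactions.
Treatment-by-covariate interactions are out of scope throughout.

### Correlated binary covariates

The three shipped parameterisations (`mist2`, `augib`, `pbc` — a pleural
infection trial with a continuous outcome, a gastrointestinal-bleeding
audit with a binary outcome, and a primary-biliary-cirrhosis trial with a
survival outcome) specify each covariate's prevalence and each pair's
joint prevalence. Covariates are generated by thresholding a multivariate
normal vector: coordinate c is cut at z(1−p_c), and the pairwise latent
correlation ρ_cd is solved (bracketed root-finding on the bivariate-normal
orthant probability, residual < 10⁻⁸) so that
P(X_c = X_d = 1) equals the stated joint prevalence exactly. Joint
prevalences must respect the Fréchet bounds of their marginals. Pairwise
solutions are assembled into a correlation matrix; if the result is not
positive semi-definite it is repaired by eigenvalue clipping at 10⁻⁸ and
rescaling to unit diagonal, with a warning when any eigenvalue moves by
more than 0.01 (none of the three shipped parameterisations needs repair;
their smallest eigenvalues are 0.64, 0.67 and 0.49).

This reproduces the first two moments of the covariate distribution; it
cannot reproduce three-way or higher dependence of the original datasets,
which is unknown. Simulated stratum frequencies therefore match real data
only up to pairwise structure.

### Calibration

The binary and survival generators are calibrated to the stated
control-arm event rates (23.6% for `augib`, or 30.1% when n ≤ 100; 40.4%
for `pbc`):

- binary: the intercept α solves mean logit⁻¹(α + η_cov) = target;
- survival: with λ = 1, the censoring cut-point c solves
  mean (1 − e^(−c·e^(η_cov))) = target.

Both averages are taken analytically over one large covariate sample
(n = 2·10⁵, seeded), so the root-finding is deterministic bisection with
no simulation noise; re-simulation reproduces the target within ±0.005 in
the test suite. The power-study treatment effect is found by stochastic
bisection on the empirical power of the covariate-adjusted analysis under
simple randomisation (coarse 500-replication evaluations, probit-scale
refinement at 2000 replications, accepted inside [0.78, 0.82]); candidate
effects share replication seeds, making the search deterministic and
monotone. For binary and survival outcomes the calibrated effect is
negative — the treatment reduces events.

### Sensitivity scaling

`scale_interactions` multiplies every interaction coefficient on the link
scale (so ratio measures are powered: an interaction hazard ratio of 0.45
scaled by 7.5 becomes (1/0.45)^7.5 ≈ 399), then the intercept/censoring is
re-calibrated to hold the control event rate. The sensitivity sweep runs
the covariate-adjusted-after-stratified-blocks null scenario at factors
{1, 2.5, 5, 7.5, 10}; we run it at n = 500, the midpoint of the sample-size
grids, since no single n is canonical.

## Randomisation schemes

- **Simple**: independent fair coin per patient.
- **Stratified permuted blocks**: within every covariate-combination
  stratum, random blocks containing block_size/2 patients per arm (block
  size 2 for the two-factor scenarios, 4 for the real-data scenarios);
  trailing blocks are truncated. Within-stratum imbalance can never exceed
  block_size/2, at any prefix of the arrival sequence.
- **Minimisation** (Pocock–Simpson, range metric, equal weights): for each
  candidate arm, sum over the new patient's covariate levels the absolute
  arm-count difference that the assignment would produce; the lower-scoring
  arm is assigned with probability 0.8 (configurable in (0.5, 1]); exact
  ties — including the first patient — fall back to a fair coin.
  Minimisation balances each factor marginally but leaves the joint
  (stratum-level) balance near that of simple randomisation, which is
  precisely why a covariate-adjusted analysis remains valid after it.

All allocators are bitwise reproducible given their input stream.

## Analysis methods

All five estimators return the treatment effect on the link scale with a
Wald standard error; rejection uses the two-sided 5% Wald test (t
reference with residual degrees of freedom for linear models, standard
normal otherwise).

1. **Covariate-adjusted**: outcome ~ treatment + each factor (main effects
   only); OLS / logistic regression / Cox PH by family.
2. **Stratified, fixed effects**: treatment + one indicator per observed
   stratum (reference dropped; the choice is irrelevant to the treatment
   effect). For continuous outcomes this is algebraically identical to
   adjusting for all covariates and all their interactions — asserted
   exactly in the tests. For binary/survival outcomes, strata with no
   outcome variation (no events, or all events) would drive their
   indicator to ±∞; the fit removes those patients first, which is the
   exact profile-likelihood limit of the diverging indicator.
3. **Stratified, random effects**: a normal random intercept per stratum.
   Continuous — linear mixed model by REML (statsmodels MixedLM). Binary —
   logistic random-intercept model fitted by adaptive Gauss–Hermite
   quadrature, 15 nodes, each stratum's integrand re-centred at its
   conditional mode (cross-checked against lme4::glmer with nAGQ=15 to
   ~10⁻⁴). Survival — Cox model with a log-normal stratum frailty:
   penalised Efron partial likelihood over (β, u) with ridge precision
   1/τ² on u, and τ² profiled by golden-section search of the
   Laplace-approximate marginal likelihood (log-scale tolerance 0.02,
   bounded by τ² ≤ 25; a boundary solution collapses to the unadjusted Cox
   fit and is reported as converged with τ² = 0). The variance criterion is
   Laplace ML; R's coxph uses a slightly different default, so τ̂² can
   differ while the treatment log-HR and its SE agree closely (verified
   against frozen coxph values, exactly so at fixed τ²).
4. **Mantel–Haenszel** (binary): pooled odds ratio with the
   Robins–Breslow–Greenland variance for the log-OR (statsmodels
   StratifiedTable); strata missing an arm carry no information and are
   excluded; the test is Wald on the log-OR rather than the CMH score test
   — the difference is negligible at these sample sizes and keeps one
   rejection rule across methods.
5. **Stratified Cox** (survival): partial likelihood with stratum-specific
   baseline hazards, treatment as the only covariate.

All Cox-type fits use a single vectorised Efron-tie partial-likelihood
Newton engine (ties are heavy here: discrete covariates plus administrative
censoring). It matches lifelines to ~10⁻⁶ on the same data; lifelines is
kept as the independent cross-check, never the implementation, so the two
routes stay distinct. A fit counts as non-converged on optimiser failure,
separation-style divergence (|coefficient| > 15 on the link scale), or a
non-finite standard error; rejection rates are reported among converged
replications, with a count-non-converged-as-non-reject rate alongside.

## Monte-Carlo engine

Each replication draws covariates once and one set of outcome noise
variates (ε, the latent logistic error, or U) once, then re-uses them for
every randomisation scheme and analysis method — common random numbers, so
method contrasts carry far less Monte-Carlo error than the individual
rates, and allocation can never leak into the outcome noise. Replication r
is seeded from SeedSequence([master_seed, scenario_tag, r]) with separate
child streams for covariates, noise and each scheme; results are
reproducible and independent of the order schemes or methods are listed.
The binomial Monte-Carlo SE of a rate r from n replications is
√(r(1−r)/n) — about 0.3% at 5000 replications and a true 5% rate.

Replication counts: the headline studies use 5000 replications; the
shipped test suite and the acceptance script run the survival scenarios at
2000 replications (tolerances widened to three Monte-Carlo SEs
accordingly) and the qualitative grid checks at 800, which keeps the whole
suite in the tens of minutes on one core.

## Design choices where the design was open

- Minimisation imbalance metric, tie handling, and first-patient rule are
  the canonical Pocock–Simpson choices (range metric, fair coin); covariate
  weights are equal.
- The power-calibration vehicle (covariate-adjusted analysis under simple
  randomisation) is a neutral baseline shared by every comparison.
- The frailty distribution is log-normal, matching the normal random
  intercept of the other families; Efron tie handling everywhere.
- Table percentages are read as proportions (67 → 0.67); ratio parameters
  enter as natural logarithms and are used exactly as printed.

## Known limitations

- Generated covariates reproduce marginal and pairwise joint prevalences
  only; real higher-order dependence is not modelled, so passing tests
  validate the method comparison under this copula, not under any
  particular real dataset.
- The frailty variance is a Laplace-approximate ML estimate; with very few
  strata it is noisy (the treatment effect is much less sensitive).
- Centre effects, >2 arms, continuous covariates, missing data, and
  treatment-by-covariate interaction are out of scope.
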