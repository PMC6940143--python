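# Methods

## The model ladder

All variants share a linear mixed-model core for an omic signal `m_ij` of
subject `i` at measurement occasion `j` (site × timepoint):

```
m_ij ~ N(mu_ij, sigma_e^2)
mu_ij = alpha + beta' x_ij + beta_expo z_ij + gamma_i + delta_j
```

`x_ij` holds sex, age, BMI, health-group dummies (healthy / COPD / IHD) and
the subject's annual background concentration of the pollutant(s) in the
model. `gamma_i` is a subject random intercept, `delta_j` a measurement-cell
random intercept indexed by the six site × timepoint cells and shared across
subjects (the per-subject reading of the occasion effect is absorbed by
`gamma_i` plus the residual and is weakly identified at one observation per
subject-cell; this is a deliberate modelling choice).

The ladder then varies three switches:

- **naive vs corrected.** Naive variants plug the observed proxy `W` in for
  the exposure. Corrected variants add the classical-error layer
  `W_ij = Z_ij + U_ij`, `U ~ N(0, sigma_U^2)` and sample the latent `Z_ij`.
  The latent exposure gets the structural model
  `Z_ij ~ N(mu_Z[site(ij)], sigma_Z^2)` with a *site-specific* mean: the
  crossover design guarantees street exposures run systematically higher
  than park exposures, and a pooled mean would over-shrink both sites toward
  the grand mean, biasing the corrected slope low (we measured ~10% downward
  bias and 87% coverage of the 95% interval with a pooled mean; with
  site-specific means the slope is unbiased and coverage is 93–97%). With a
  single site the model reduces to the pooled form.
- **univariate vs multi-response.** The multiomics variants make the
  K-vector of features per record multivariate normal with covariance
  `Sigma_e` whose precision gets a Wishart prior, so feature dependence is
  estimated, not ignored.
- **single vs multi-exposure.** The multiexposure variants treat the
  pollutant vector jointly: `beta_expo` becomes a K×P matrix, the latent `Z`
  a P-vector per record, and the precisions of `Sigma_Z` (and `Sigma_U`,
  when it is sampled) get Wishart priors.

### Priors and their parametrization

- Regression coefficients: independent `N(0, 1000)`. This is only vague on a
  standardized scale, so responses, exposures and continuous covariates are
  z-scored internally and the retained draws of coefficients, exposure
  summaries and residual variances are mapped back to the original units
  (random-effect blocks are reported on the standardized-response scale; the
  scaling constants travel with the draws).
- Scalar precisions (residual, random effects, exposure, error):
  `Gamma(shape 0.01, rate 0.01)`, i.e. inverse-gamma on the variances.
- Precision matrices: `Wishart(df = dimension, rate matrix 0.01 * I)` in the
  convention where the density carries `exp(-tr(R Q)/2)` — the vague choice:
  the posterior scatter is `0.01*I + sum of outer products`, so the prior
  contributes negligibly at n = 360. (Reading the 0.01 as the *scale* matrix
  instead would add `100*I` to the scatter and shrink a residual correlation
  of 0.7 to ~0.55 at this sample size — demonstrably not a vague prior.)
- Measurement-error variance: fixable to a known value (`PriorConfig
  .error_variance`), which is the identifiable configuration when no
  replicate measurements exist; if left free it is sampled under the
  gamma/Wishart prior and the fit warns that it is only weakly identified.
- `PriorConfig.noise_variance` can fix `sigma_e^2`; combined with
  `include_random_effects=False` the sampler draws i.i.d. from the exact
  conjugate normal posterior, which is how the engine is validated against
  the closed-form oracle.

### The samplers

Blocked Gibbs with conjugate full conditionals only (no Metropolis steps):
the full fixed-effect + exposure-coefficient vector is drawn jointly as one
multivariate normal per sweep (Kronecker structure `Qe ⊗ D'D` in the
multi-response case); random effects are drawn per level with a shared
Cholesky factor; scalar precisions by gamma updates; precision matrices by
Wishart updates; latent exposures per record from a shared-precision normal
conditional, vectorized over records. Chains get independent sub-seeds from
one `SeedSequence`, so runs are reproducible bit-for-bit. Every retained
covariance draw is checked symmetric positive-definite, every variance draw
positive. Latent-exposure draws are stored as running posterior mean/SD per
record rather than full trajectories.

A vectorized batch sampler (`fit_univariate_batch`) runs many independent
naive univariate fits that share one design — statistically identical to
looping the single-feature sampler, but with all updates batched across
features, which is what makes the replicated FDR studies tractable.

Defaults: 4 chains × 5000 iterations, 2000 burn-in, thin 1. The recovery
experiments in `trapme.experiments` use 2 chains × 2500 (burn-in 1000), and
the replicated FDR/coverage studies 1 short chain per fit (800/300 and
1500/500 draws); these sizes keep each study at desk scale while leaving
Monte-Carlo error well inside the tolerances being tested, as the
conjugate-oracle and reproducibility checks confirm.

## The synthetic-data generator

Emulates the statistical structure the models assume, with known truth for
recovery testing: 60 subjects in three health groups of 20 (sex Bernoulli,
age/BMI truncated normals at 60±8 y and 27±4 kg/m²); exactly 6 records per
subject (2 sites × 3 timepoints); true exposures multivariate normal on a
standardized log-like scale with a default cross-pollutant correlation
matrix (PM₂.₅–PM₁₀ 0.8, PMs–black carbon 0.7, NO₂–others 0.5) and a
street−park mean offset of 1 SD; classical error added per record with
configurable scalar or matrix covariance; omic features from the mixed model
above, optionally with a non-diagonal residual covariance across features.
Effect sizes for recovery studies span {0, 0.5, 1.0} on the standardized
exposure scale — null plus clearly detectable at n = 360.

What it does **not** emulate: mass-spectrometry intensity distributions,
missingness, batch effects, peak shapes, or non-Gaussian exposure tails. A
passing recovery test therefore certifies the estimator under the model
class, not robustness to instrument artefacts.

## Decision layer

- Bayesian p-value: two-sided tail posterior probability
  `2·min(Pr(beta>0), Pr(beta<0))` from draw proportions.
- Bayesian FDR at level 0.05: sort the per-test values ascending and reject
  the largest prefix whose running mean stays ≤ level (the
  posterior-expected-FDR rule). Applied to univariate pipelines only — the
  multivariate variants evaluate all hypotheses jointly in one model, so
  their decision is the direct `bayes_p ≤ level` per coefficient.
- Pre-screen: per-feature frequentist OLS with fixed subject intercepts
  (absorbing all subject-constant covariates) and cell intercepts, keeping
  features with exposure p < 0.5. This is a pragmatic surrogate for a
  pre-existing frequentist analysis stage; its operating characteristics
  (≈50% null retention, >99% retention of strong signals) are verified in
  the tests.
- Convergence gate: classic Gelman-Rubin potential scale reduction plus bulk
  ESS (via arviz) per coefficient block.

### Known limitation: realized FDR of the tail-probability plug-in

The FDR rule above controls the *posterior-expected* FDR when fed genuine
posterior null probabilities. When each feature is fit separately with vague
priors, the two-sided tail probability of a null feature is an approximately
calibrated frequentist p-value — Uniform(0,1) under the null — not a
posterior probability of the null (which would concentrate near 1). Feeding
uniform values into the running-mean rule over-rejects: with 20 strong
signals (tail values ≈ 0) among 180 nulls at level 0.05, the rejection
prefix admits roughly the 28–30 smallest null values, and the realized false
discovery proportion is ≈ 0.6 rather than 0.05. The replicated study in
`analysis/04_screening_fdr_coverage.py` measures exactly this. The samplers
themselves are calibrated — the corrected model's 95% credible intervals
cover the true effect 93–97% of the time over replicates — so the gap is a
property of the decision rule, which would need cross-feature shrinkage or an
explicit null/alternative mixture to supply honest posterior null
probabilities. That extension is out of scope here and the behaviour is
reported as measured.

### Other numerical choices and limitations

- Constant design columns are dropped with a warning; rank-deficient designs
  and multi-response fits with more features than records are refused with
  actionable messages.
- `error_variance = 0` short-circuits the latent block (`Z = W` exactly),
  making the corrected sampler degenerate cleanly to the naive one; K = 1
  multi-response and P = 1 multi-exposure fits take literally the same code
  path as the univariate sampler, so those degeneracies are exact.
- Under strongly correlated exposures with independent errors, the corrected
  multiexposure posterior develops a long flat ridge: the coefficient *sum*
  is well identified but its split across nearly collinear latent exposures
  is not, and chains traverse the ridge slowly. The analysis drivers report
  the sum in that regime; R-hat flags the slow direction.
- Berkson-type error and spatial dependence between pollutants are
  deliberate non-features; the error layer is a hook where a Berkson variant
  could later be added.
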