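# trapme — Bayesian measurement-error models for air-pollution / omics studies

Personal exposure to traffic-related air pollution (TRAP: NO₂, PM₂.₅, PM₁₀,
black carbon) is measured with portable samplers and stationary monitors, so
what reaches an analysis is an error-prone proxy *W* of the true exposure *Z*.
Under classical additive error, *W = Z + U* with *U ⟂ Z*, regressing an omic
signal on *W* attenuates the slope by

    λ = σ²_Z / (σ²_Z + σ²_U),        Λ = Σ_Z (Σ_Z + Σ_U)⁻¹  (multivariate),

and with correlated pollutants the bias can push a null coefficient *away*
from zero. `trapme` implements a ladder of Bayesian hierarchical models for a
randomized crossover trial (each subject walks a polluted street and a
traffic-free park; blood is sampled before, +2 h and +24 h after each walk):

    m_ij ~ N(μ_ij, σ²_e)          (or MVN with Σ_e across features)
    μ_ij = α + βᵀx_ij + β_expo z_ij + γ_i + δ_j
    W_ij = Z_ij + U_ij,   U ~ N(0, σ²_U)          (corrected variants)
    Z_ij ~ N(μ_Z[site], σ²_Z)                      (latent exposure model)

with subject random intercepts γ, site×timepoint random intercepts δ, vague
N(0, 1000) coefficient priors, Gamma(0.01, 0.01) precision priors and Wishart
priors on precision matrices. All six variants (naive/corrected ×
uni/multi-response × uni/multi-exposure) are fit by bespoke blocked Gibbs
samplers built entirely from conjugate full conditionals. The decision layer
provides two-sided Bayesian p-values, a Bayesian FDR rule, posterior
summaries with 95% credible intervals, Gelman-Rubin/ESS diagnostics, and a
frequentist pre-screen for metabolome-scale feature sets. Because raw trial
data of this kind are typically not deposited, the package ships a
synthetic-data generator that emulates the full crossover design (60 subjects
in three health groups, four correlated pollutants, mixed-model omics) with
known ground truth, so every claim is testable by parameter recovery.

Intended users: biostatisticians and exposure epidemiologists who want
error-corrected effect estimates for omic outcomes, and anyone needing a
tested reference implementation of latent-exposure Gibbs samplers.

## Worked example

```python
import numpy as np
from trapme import (SimulationConfig, simulate_dataset, ModelSpec, PriorConfig,
                    MCMCConfig, fit_univariate, fit_corrected_univariate,
                    summarize, attenuation_factor)

cfg = SimulationConfig(n_per_group=20, n_features=1, pollutants=("NO2",),
                       Sigma_Z=np.eye(1), error_cov=1.0,       # sigma_U^2 = 1
                       beta_expo=np.array([[1.0]]), seed=1)
ds, truth = simulate_dataset(cfg)                              # 360 records

mcmc = MCMCConfig(n_chains=2, n_iter=2500, n_burnin=1000, seed=2)
naive = fit_univariate(ds, ModelSpec("naive_uni", ds.feature_ids, ["NO2"]), mcmc)
corr  = fit_corrected_univariate(
    ds, ModelSpec("corrected_uni", ds.feature_ids, ["NO2"],
                  priors=PriorConfig(error_variance=1.0)), mcmc)

print("lambda =", attenuation_factor(1.0, 1.0))
print(summarize(naive)[["posterior_mean", "cri_lower_95", "cri_upper_95"]])
print(summarize(corr)[["posterior_mean", "cri_lower_95", "cri_upper_95"]])
```

Output (true effect β = 1):

```
lambda = 0.5
   posterior_mean  cri_lower_95  cri_upper_95
0        0.452611      0.354101      0.549968
   posterior_mean  cri_lower_95  cri_upper_95
0        0.975974      0.752607      1.220669
```

The naive fit lands on λβ = 0.5 — the attenuation the error theory predicts —
while the corrected fit (error variance known) recovers β = 1 with a wider
credible interval that honestly carries the extra uncertainty.

The numbered drivers under `analysis/` run the full set of studies (design
moments, attenuation grid, multivariate variants, screening/FDR/coverage
operating characteristics) and write their tables under `results/`. A
`trapme` console script exposes `simulate`, `screen`, `fit`, `infer` and
`recover` subcommands for shell use; `docs/methods.md` documents the models,
priors, numerical choices and known limitations.

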