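"""Synthetic-recovery experiments at the trial's design scale.

Each function simulates data under stated study conditions (60 subjects x 6
records unless noted), runs the relevant model variants, and returns the
measured quantities together with the closed-form expectations from
:mod:`trapme.oracles`. These are the computations behind the ``analysis/``
drivers and the acceptance checks; MCMC settings are reduced relative to the
package defaults to keep each experiment at desk scale (a few minutes on one
CPU) while leaving Monte-Carlo error well inside the tolerances under test.
"""

from __future__ import annotations

import numpy as np

from . import gibbs, inference, oracles
from .models import MCMCConfig, ModelSpec, PriorConfig
from .synthetic import SimulationConfig, simulate_dataset


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _beta_first(n_features: int, P: int, value: float) -> np.ndarray:
    b = np.zeros((n_features, P))
    b[0, 0] = value
    return b


def attenuation_experiment(
    seed: int = 1,
    n_per_group: int = 20,
    sigma_u2: float = 1.0,
    beta: float = 1.0,
    mcmc_kwargs: dict | None = None,
) -> dict:
    """Univariate attenuation and its correction.

    One feature with true exposure effect ``beta`` on a single pollutant with
    unit exposure variance and error variance ``sigma_u2``. The naive model
    (proxy W plugged in) should recover ``lambda * beta`` with
    ``lambda = 1 / (1 + sigma_u2)``; the corrected model with sigma_U^2 fixed
    at truth should recover ``beta`` with a wider credible interval.
    """
    seeds = _sub_seeds(seed, 3)
    cfg = SimulationConfig(
        n_per_group=n_per_group,
        n_features=1,
        pollutants=("NO2",),
        Sigma_Z=np.eye(1),
        error_cov=sigma_u2,
        beta_expo=np.array([[beta]]),
        seed=seeds[0],
    )
    ds, truth = simulate_dataset(cfg)
    mk = dict(n_chains=2, n_iter=2500, n_burnin=1000)
    mk.update(mcmc_kwargs or {})
    feat = ds.feature_ids[0]

    naive = gibbs.fit_univariate(
        ds,
        ModelSpec("naive_uni", [feat], ["NO2"]),
        MCMCConfig(seed=seeds[1], **mk),
    )
    corrected = gibbs.fit_corrected_univariate(
        ds,
        ModelSpec("corrected_uni", [feat], ["NO2"],
                  priors=PriorConfig(error_variance=sigma_u2)),
        MCMCConfig(seed=seeds[2], **mk),
    )

    out = {"lambda": oracles.attenuation_factor(1.0, sigma_u2), "beta_true": beta,
           "n_records": ds.n_records}
    for label, draws in (("naive", naive), ("corrected", corrected)):
        b = draws.beta_expo_draws()
        lo, hi = np.quantile(b, [0.025, 0.975])
        out[f"{label}_mean"] = float(b.mean())
        out[f"{label}_sd"] = float(b.std())
        out[f"{label}_cri"] = (float(lo), float(hi))
        out[f"{label}_cri_width"] = float(hi - lo)
    return out


def conjugate_check(seed: int = 1, mcmc_kwargs: dict | None = None) -> dict:
    """Gibbs vs closed-form conjugate posterior with the hierarchy switched off.

    Random effects disabled in both truth and fit, residual variance fixed at
    truth: the Gibbs sampler then draws i.i.d. from the exact normal
    posterior, so means and SDs must agree to Monte-Carlo accuracy.
    """
    seeds = _sub_seeds(seed, 2)
    sigma_e2 = 1.0
    cfg = SimulationConfig(
        n_per_group=20, n_features=1, pollutants=("NO2",), Sigma_Z=np.eye(1),
        error_cov=0.0, sigma_e2=sigma_e2, sigma_gamma2=1e-12, sigma_delta2=1e-12,
        beta_expo=np.array([[1.0]]), seed=seeds[0],
    )
    ds, truth = simulate_dataset(cfg)
    feat = ds.feature_ids[0]
    spec = ModelSpec(
        "naive_uni", [feat], ["NO2"],
        priors=PriorConfig(noise_variance=sigma_e2),
        standardize=False,
        include_random_effects=False,
    )
    mk = dict(n_chains=4, n_iter=5000, n_burnin=2000)
    mk.update(mcmc_kwargs or {})
    draws = gibbs.fit(ds, spec, MCMCConfig(seed=seeds[1], **mk))

    # closed-form reference on the identical design
    d = gibbs._build_design(ds, spec)
    D = np.concatenate([d.X, d.W], axis=1)
    mean, cov = oracles.conjugate_posterior_oracle(
        d.y[:, 0], D, spec.priors.coef_prior_variance, sigma_e2
    )
    sd = np.sqrt(np.diag(cov))

    theta = np.concatenate(
        [draws.stacked("alpha")[:, None, 0],
         draws.stacked("beta_cov")[:, :, 0],
         draws.stacked("beta_expo")[:, :, 0]],
        axis=1,
    )
    gibbs_mean = theta.mean(axis=0)
    gibbs_sd = theta.std(axis=0)
    denom = np.maximum(np.abs(mean), sd)
    return {
        "coef_names": ["alpha"] + draws.covariate_names + ["beta_expo"],
        "exact_mean": mean, "exact_sd": sd,
        "gibbs_mean": gibbs_mean, "gibbs_sd": gibbs_sd,
        "mean_rel_err_pct": 100 * np.abs(gibbs_mean - mean) / denom,
        "sd_rel_err_pct": 100 * np.abs(gibbs_sd - sd) / sd,
        "n_records": ds.n_records,
    }


def degeneracy_experiment(seed: int = 1, mcmc_kwargs: dict | None = None) -> dict:
    """Limiting equivalences of the model ladder on one shared dataset.

    corrected(sigma_U^2 = 0) vs naive (statistical agreement within combined
    Monte-Carlo error); multiomics with K=1 and multiexpo with P=1 vs the
    univariate fit (identical draws: they reduce to the same sampler).
    """
    seeds = _sub_seeds(seed, 3)
    cfg = SimulationConfig(
        n_per_group=20, n_features=1, pollutants=("NO2",), Sigma_Z=np.eye(1),
        error_cov=0.25, beta_expo=np.array([[1.0]]), seed=seeds[0],
    )
    ds, _ = simulate_dataset(cfg)
    feat = ds.feature_ids[0]
    mk = dict(n_chains=2, n_iter=2500, n_burnin=1000)
    mk.update(mcmc_kwargs or {})
    mc = MCMCConfig(seed=seeds[1], **mk)

    naive = gibbs.fit_univariate(ds, ModelSpec("naive_uni", [feat], ["NO2"]), mc)
    corrected0 = gibbs.fit_corrected_univariate(
        ds, ModelSpec("corrected_uni", [feat], ["NO2"],
                      priors=PriorConfig(error_variance=0.0)),
        MCMCConfig(seed=seeds[2], **mk),
    )
    multi_k1 = gibbs.fit_multiomics(ds, ModelSpec("naive_multiomics", [feat], ["NO2"]), mc)
    multi_p1 = gibbs.fit_multiexposure(ds, ModelSpec("naive_multiexpo", [feat], ["NO2"]), mc)

    def mcse(draws):
        b = draws.params["beta_expo"][:, :, 0, 0]
        ess = max(inference.effective_sample_size(b), 10.0)
        return float(b.std() / np.sqrt(ess))

    bn = naive.beta_expo_draws()
    bc = corrected0.beta_expo_draws()
    return {
        "naive_mean": float(bn.mean()),
        "corrected0_mean": float(bc.mean()),
        "corrected0_gap": float(abs(bn.mean() - bc.mean())),
        "corrected0_mc_tol": float(4 * np.sqrt(mcse(naive) ** 2 + mcse(corrected0) ** 2)),
        "multiomics_k1_max_abs_diff": float(
            np.max(np.abs(multi_k1.params["beta_expo"] - naive.params["beta_expo"]))
        ),
        "multiexpo_p1_max_abs_diff": float(
            np.max(np.abs(multi_p1.params["beta_expo"] - naive.params["beta_expo"]))
        ),
        "n_records": ds.n_records,
    }


def multivariate_attenuation_experiment(
    seed: int = 1,
    rho_z: float = 0.0,
    beta: tuple[float, float] = (1.0, 0.0),
    mcmc_kwargs: dict | None = None,
) -> dict:
    """Two-pollutant attenuation: naive vs corrected against Lambda' beta.

    With Sigma_Z = [[1, rho], [rho, 1]] and Sigma_U = I fixed at truth, the
    naive multiexposure fit should center on ``Lambda' beta`` with
    ``Lambda = Sigma_Z (Sigma_Z + Sigma_U)^{-1}`` (cross-contamination of the
    null coefficient when rho != 0), while the corrected fit recovers beta.
    """
    seeds = _sub_seeds(seed, 3)
    Sigma_Z = np.array([[1.0, rho_z], [rho_z, 1.0]])
    Sigma_U = np.eye(2)
    cfg = SimulationConfig(
        n_per_group=20, n_features=1, pollutants=("NO2", "PM25"),
        Sigma_Z=Sigma_Z, error_cov=Sigma_U,
        beta_expo=np.asarray(beta, dtype=float)[None, :], seed=seeds[0],
    )
    ds, _ = simulate_dataset(cfg)
    feat = ds.feature_ids[0]
    mk = dict(n_chains=2, n_iter=2500, n_burnin=1000)
    mk.update(mcmc_kwargs or {})

    naive = gibbs.fit_multiexposure(
        ds, ModelSpec("naive_multiexpo", [feat], ["NO2", "PM25"]),
        MCMCConfig(seed=seeds[1], **mk),
    )
    corrected = gibbs.fit_multiexposure(
        ds, ModelSpec("corrected_multiexpo", [feat], ["NO2", "PM25"],
                      priors=PriorConfig(error_variance=Sigma_U)),
        MCMCConfig(seed=seeds[2], **mk),
    )
    Lam = oracles.attenuation_factor(Sigma_Z, Sigma_U)
    return {
        "lambda_matrix": Lam,
        "naive_expected": Lam.T @ np.asarray(beta, dtype=float),
        "beta_true": np.asarray(beta, dtype=float),
        "naive_mean": naive.stacked("beta_expo")[:, :, 0].mean(axis=0),
        "corrected_mean": corrected.stacked("beta_expo")[:, :, 0].mean(axis=0),
        "n_records": ds.n_records,
    }


def covariance_recovery_experiment(
    seed: int = 1, rho: float = 0.7, mcmc_kwargs: dict | None = None
) -> dict:
    """Residual-correlation recovery with a three-feature multivariate response.

    Features 1-2 share residual correlation ``rho``; feature 3 is independent.
    The naive multiomics fit's posterior mean of the Sigma_e correlations
    should recover the generating matrix.
    """
    seeds = _sub_seeds(seed, 2)
    Sigma_e = np.eye(3)
    Sigma_e[0, 1] = Sigma_e[1, 0] = rho
    cfg = SimulationConfig(
        n_per_group=20, n_features=3, pollutants=("NO2",), Sigma_Z=np.eye(1),
        error_cov=0.25, Sigma_e=Sigma_e,
        beta_expo=np.array([[0.5], [0.0], [0.0]]), seed=seeds[0],
    )
    ds, _ = simulate_dataset(cfg)
    mk = dict(n_chains=2, n_iter=2500, n_burnin=1000)
    mk.update(mcmc_kwargs or {})
    draws = gibbs.fit_multiomics(
        ds, ModelSpec("naive_multiomics", ds.feature_ids, ["NO2"]),
        MCMCConfig(seed=seeds[1], **mk),
    )
    Se = draws.stacked("Sigma_e")
    dstd = np.sqrt(np.einsum("tkk->tk", Se))
    corr = Se / (dstd[:, :, None] * dstd[:, None, :])
    return {
        "true_corr": rho,
        "posterior_corr": corr.mean(axis=0),
        "posterior_corr_12": float(corr[:, 0, 1].mean()),
        "n_records": ds.n_records,
    }


def fdr_experiment(
    seed: int = 1,
    n_replicates: int = 50,
    n_null: int = 180,
    n_signal: int = 20,
    signal_beta: float = 1.0,
    level: float = 0.05,
    screen_threshold: float = 0.5,
    mcmc_kwargs: dict | None = None,
) -> dict:
    """Realized false discovery proportion of the screening + Bayesian-FDR pipeline.

    Each replicate: simulate ``n_null + n_signal`` features (signals carry
    ``signal_beta`` on the first pollutant), pre-screen at p < 0.5, fit the
    naive univariate model to every surviving feature (vectorized batch),
    compute two-sided Bayesian p-values and apply the Bayesian FDR at
    ``level``. Reports the replicate-averaged false discovery proportion and
    power against the generator's truth.
    """
    mk = dict(n_chains=1, n_iter=800, n_burnin=300)
    mk.update(mcmc_kwargs or {})
    seeds = _sub_seeds(seed, n_replicates)
    F = n_null + n_signal
    beta = np.zeros((F, 1))
    beta[:n_signal, 0] = signal_beta
    fdp, power, n_rej = [], [], []
    for rep_seed in seeds:
        s0, s1 = _sub_seeds(rep_seed, 2)
        cfg = SimulationConfig(
            n_per_group=20, n_features=F, pollutants=("NO2",), Sigma_Z=np.eye(1),
            error_cov=1.0, beta_expo=beta, seed=s0,
        )
        ds, truth = simulate_dataset(cfg)
        kept = inference.screen_features(ds, "NO2", screen_threshold)
        batch = gibbs.fit_univariate_batch(
            ds, kept, "NO2", MCMCConfig(seed=s1, **mk)
        )
        pvals = np.array(
            [inference.bayesian_pvalue(batch.beta_expo[:, :, j].ravel())
             for j in range(len(kept))]
        )
        rej = inference.bayesian_fdr(pvals, level)
        is_signal = np.array([ds.feature_ids.index(f) < n_signal for f in kept])
        R = int(rej.sum())
        V = int((rej & ~is_signal).sum())
        fdp.append(V / max(R, 1))
        power.append((rej & is_signal).sum() / n_signal)
        n_rej.append(R)
    return {
        "realized_fdr": float(np.mean(fdp)),
        "power": float(np.mean(power)),
        "mean_rejections": float(np.mean(n_rej)),
        "n_replicates": n_replicates,
        "level": level,
    }


def coverage_experiment(
    seed: int = 1,
    n_replicates: int = 100,
    beta: float = 1.0,
    sigma_u2: float = 1.0,
    mcmc_kwargs: dict | None = None,
) -> dict:
    """Frequentist coverage of the corrected model's 95% credible interval.

    Replicated single-feature datasets with known error variance; the
    fraction of replicates whose 95% CrI for the exposure coefficient covers
    the generating value should sit near 95%.
    """
    mk = dict(n_chains=1, n_iter=1500, n_burnin=500)
    mk.update(mcmc_kwargs or {})
    seeds = _sub_seeds(seed, n_replicates)
    hits = 0
    for rep_seed in seeds:
        s0, s1 = _sub_seeds(rep_seed, 2)
        cfg = SimulationConfig(
            n_per_group=20, n_features=1, pollutants=("NO2",), Sigma_Z=np.eye(1),
            error_cov=sigma_u2, beta_expo=np.array([[beta]]), seed=s0,
        )
        ds, _ = simulate_dataset(cfg)
        draws = gibbs.fit_corrected_univariate(
            ds, ModelSpec("corrected_uni", [ds.feature_ids[0]], ["NO2"],
                          priors=PriorConfig(error_variance=sigma_u2)),
            MCMCConfig(seed=s1, **mk),
        )
        lo, hi = np.quantile(draws.beta_expo_draws(), [0.025, 0.975])
        hits += int(lo <= beta <= hi)
    return {
        "coverage": hits / n_replicates,
        "n_replicates": n_replicates,
        "beta_true": beta,
    }


def screening_experiment(
    seed: int = 1,
    n_null: int = 1000,
    n_signal: int = 100,
    signal_beta: float = 1.0,
    threshold: float = 0.5,
) -> dict:
    """Retention behaviour of the p < 0.5 pre-screen.

    Pure-noise features should be retained at about the threshold rate (their
    p-values are uniform); strong-signal features essentially always.
    """
    F = n_null + n_signal
    beta = np.zeros((F, 1))
    beta[n_null:, 0] = signal_beta
    cfg = SimulationConfig(
        n_per_group=20, n_features=F, pollutants=("NO2",), Sigma_Z=np.eye(1),
        error_cov=1.0, beta_expo=beta, seed=_sub_seeds(seed, 1)[0],
    )
    ds, _ = simulate_dataset(cfg)
    kept = set(inference.screen_features(ds, "NO2", threshold))
    null_ids = ds.feature_ids[:n_null]
    signal_ids = ds.feature_ids[n_null:]
    return {
        "null_retention": sum(f in kept for f in null_ids) / n_null,
        "signal_retention": sum(f in kept for f in signal_ids) / n_signal,
        "n_null": n_null,
        "n_signal": n_signal,
        "threshold": threshold,
    }
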