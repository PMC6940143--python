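"""Posterior draws -> association decisions.

Implements the decision layer of the pipeline: two-sided Bayesian p-values as
tail posterior probabilities, the Bayesian false-discovery-rate rule (reject
the largest prefix of ascending posterior null evidence whose running mean
stays below the nominal level), posterior summaries with equal-tailed 95%
credible intervals, the Gelman-Rubin convergence gate, and the frequentist
pre-screening stage that thins a metabolome-wide feature set before the
Bayesian fits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CELLS, CrossoverDataset
from .gibbs import BatchUnivariateDraws
from .models import PosteriorDraws

__all__ = [
    "bayesian_pvalue",
    "bayesian_fdr",
    "summarize",
    "gelman_rubin",
    "effective_sample_size",
    "diagnostics",
    "screen_features",
    "screen_pvalues",
]


def bayesian_pvalue(draws: np.ndarray) -> float:
    """Two-sided tail posterior probability: 2 * min(Pr(theta>0), Pr(theta<0)).

    Estimated by draw proportions; invariant to draw order and to any
    sign-preserving monotone rescaling of the draws.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("empty draw set")
    p_pos = np.mean(draws > 0)
    p_neg = np.mean(draws < 0)
    return float(min(1.0, 2.0 * min(p_pos, p_neg)))


def bayesian_fdr(pvalues, level: float = 0.05) -> np.ndarray:
    """Posterior-expected-FDR rule: reject the largest ascending prefix whose
    running mean of posterior null evidence is <= level.

    Returns a boolean rejection vector aligned with the input order. The
    rejection set is monotone: if a value is rejected, so is every smaller
    one; the number of rejections is non-decreasing in ``level``.
    """
    p = np.asarray(pvalues, dtype=float)
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    running = np.cumsum(p[order]) / np.arange(1, p.size + 1)
    ok = np.nonzero(running <= level)[0]
    reject = np.zeros(p.size, dtype=bool)
    if ok.size:
        reject[order[: ok[-1] + 1]] = True
    return reject


def _summary_row(draws: np.ndarray, level: float) -> dict:
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {
        "posterior_mean": float(np.mean(draws)),
        "posterior_sd": float(np.std(draws)),
        "cri_lower_95": float(lo),
        "cri_upper_95": float(hi),
        "bayes_p": bayesian_pvalue(draws),
    }


def summarize(draws: PosteriorDraws | BatchUnivariateDraws, level: float = 0.05) -> pd.DataFrame:
    """Association table: one row per feature x pollutant.

    Univariate variants are corrected for multiple testing with the Bayesian
    FDR across the table's rows; multivariate variants assess all hypotheses
    jointly and need no such correction, so their flag is the direct decision
    ``bayes_p <= level``.
    """
    rows = []
    if isinstance(draws, BatchUnivariateDraws):
        variant = draws.variant
        for j, f in enumerate(draws.feature_ids):
            row = {"feature_id": f, "pollutant_id": draws.pollutant_id}
            row.update(_summary_row(draws.beta_expo[:, :, j].ravel(), level))
            rows.append(row)
    else:
        variant = draws.spec.variant
        for pi, pol in enumerate(draws.pollutant_ids):
            for fi, f in enumerate(draws.feature_ids):
                row = {"feature_id": f, "pollutant_id": pol}
                row.update(_summary_row(draws.stacked("beta_expo")[:, pi, fi], level))
                rows.append(row)
    table = pd.DataFrame(rows)
    if variant.endswith("_uni"):
        table["fdr_significant"] = bayesian_fdr(table["bayes_p"].to_numpy(), level)
    else:
        table["fdr_significant"] = table["bayes_p"] <= level
    table["model_variant"] = variant
    return table


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor of one scalar parameter.

    ``chains`` has shape (n_chains, n_draws). Classic between/within variance
    decomposition: values near 1 indicate the chains are sampling the same
    distribution.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    within = chains.var(axis=1, ddof=1).mean()
    between_over_n = chains.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    v_hat = (n - 1) / n * within + between_over_n
    return float(np.sqrt(v_hat / within))


def effective_sample_size(chains: np.ndarray) -> float:
    """Bulk effective sample size (delegates to arviz)."""
    import arviz as az

    return float(az.ess(np.asarray(chains, dtype=float)))


def diagnostics(draws: PosteriorDraws) -> pd.DataFrame:
    """R-hat and effective sample size for every scalar-coefficient block."""
    rows = []
    for pi, pol in enumerate(draws.pollutant_ids):
        for fi, f in enumerate(draws.feature_ids):
            ch = draws.params["beta_expo"][:, :, pi, fi]
            rows.append(
                {
                    "parameter": f"beta_expo[{pol},{f}]",
                    "rhat": gelman_rubin(ch) if ch.shape[0] > 1 else np.nan,
                    "ess_bulk": effective_sample_size(ch),
                }
            )
    for name in ("sigma_gamma2", "sigma_delta2", "sigma_e2"):
        if name in draws.params:
            ch = draws.params[name]
            rows.append(
                {
                    "parameter": name,
                    "rhat": gelman_rubin(ch) if ch.shape[0] > 1 else np.nan,
                    "ess_bulk": effective_sample_size(ch),
                }
            )
    return pd.DataFrame(rows)


def _screen_design(data: CrossoverDataset, pollutant: str) -> tuple[np.ndarray, int]:
    """Fixed-effects screening design: subject intercepts, cell intercepts, exposure."""
    rec = data.records
    subj = pd.get_dummies(rec["subject_id"]).to_numpy(float)
    labels = rec["site"].astype(str) + "_" + rec["timepoint"].astype(str)
    cells = pd.get_dummies(pd.Categorical(labels, categories=list(CELLS))).to_numpy(float)
    w = rec[f"W_{pollutant}"].to_numpy(float)[:, None]
    X = np.concatenate([subj, cells[:, 1:], w], axis=1)
    return X, X.shape[1] - 1  # exposure column index


def screen_pvalues(data: CrossoverDataset, pollutant: str) -> pd.Series:
    """Per-feature frequentist p-value for the exposure term.

    Covariate adjustment is by fixed subject intercepts (which absorb all
    subject-constant covariates: sex, age, BMI, group, annual background) plus
    site x timepoint cell intercepts; the exposure t-test is vectorized across
    features since the design is shared.
    """
    X, e_col = _screen_design(data, pollutant)
    Y = data.omics.to_numpy(float).T  # (n, F)
    n, q = X.shape
    if n <= q:
        raise ValueError(f"screening needs more records ({n}) than parameters ({q})")
    XtX_inv = np.linalg.pinv(X.T @ X)
    coefs = XtX_inv @ (X.T @ Y)            # (q, F)
    resid = Y - X @ coefs
    dof = n - np.linalg.matrix_rank(X)
    s2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(s2 * XtX_inv[e_col, e_col])
    tstat = coefs[e_col] / se
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    return pd.Series(pvals, index=data.omics.index, name=f"p_{pollutant}")


def screen_features(data: CrossoverDataset, pollutant: str, threshold: float = 0.5) -> list[str]:
    """Pre-selection stage: keep features whose exposure p-value is < threshold.

    The liberal default of 0.5 is meant to discard only clearly null features
    while keeping anything with a hint of signal for the Bayesian fits.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    p = screen_pvalues(data, pollutant)
    return list(p.index[p < threshold])
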