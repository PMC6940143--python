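"""Blocked Gibbs samplers for the hierarchical exposure-outcome model ladder.

All variants share one linear predictor per record ``r`` and feature ``k``:

    m_rk ~ N(mu_rk, .)         mu_rk = alpha_k + beta_k' x_r + betaexpo_k' z_r
                                        + gamma_k[subject(r)] + delta_k[cell(r)]

- *naive* variants plug the observed proxy ``W`` in for the exposure ``z``;
- *corrected* variants add the classical-error layer ``W_r = Z_r + U_r``,
  ``U ~ N(0, sigma_U^2)`` (or ``Sigma_U``), sample the latent ``Z_r`` from its
  normal full conditional, and give ``Z`` the structural model
  ``Z_r ~ N(mu_Z[site(r)], sigma_Z^2)`` (vector analogue with ``Sigma_Z``) —
  the exposure mean is site-specific because the crossover design makes
  street-walk exposures systematically higher than park-walk ones;
- *multiomics* variants make the residual multivariate across features with
  covariance ``Sigma_e`` under a Wishart prior on its precision;
- *multiexpo* variants make the exposure (and its error) multivariate across
  pollutants with Wishart priors on the precisions of ``Sigma_Z``/``Sigma_U``.

Every full conditional is conjugate — normal for coefficients, random effects
and latent exposures, gamma for scalar precisions, Wishart for precision
matrices — so the sweep needs no Metropolis steps. Responses, exposures and
continuous covariates are z-scored internally (the N(0, 1000) coefficient
prior is only weakly informative on that scale) and the retained draws of the
coefficient, exposure and residual blocks are mapped back to the original data
scale before being returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .datatypes import CELLS, CrossoverDataset
from .models import MCMCConfig, ModelSpec, PosteriorDraws, PriorConfig

__all__ = [
    "fit",
    "fit_univariate",
    "fit_corrected_univariate",
    "fit_multiomics",
    "fit_multiexposure",
    "fit_univariate_batch",
    "latent_z_conditional",
    "BatchUnivariateDraws",
]


# ---------------------------------------------------------------------------
# linear-algebra helpers

def _draw_mvn_prec(prec: np.ndarray, b: np.ndarray, rng) -> np.ndarray:
    """One draw from N(prec^-1 b, prec^-1)."""
    L = np.linalg.cholesky(prec)
    mean = solve_triangular(L.T, solve_triangular(L, b, lower=True), lower=False)
    return mean + solve_triangular(L.T, rng.standard_normal(b.shape[0]), lower=False)


def _draw_mvn_prec_many(prec: np.ndarray, B: np.ndarray, rng) -> np.ndarray:
    """Rows of B are separate linear terms sharing one precision matrix."""
    L = np.linalg.cholesky(prec)
    mean = solve_triangular(L.T, solve_triangular(L, B.T, lower=True), lower=False)
    noise = solve_triangular(L.T, rng.standard_normal(B.T.shape), lower=False)
    return (mean + noise).T

def _wishart_precision(df0: float, rate_diag: float, scatter: np.ndarray, n: int, rng):
    """Posterior Wishart draw of a precision matrix (JAGS dwish convention)."""
    dim = scatter.shape[0]
    scale = np.linalg.inv(rate_diag * np.eye(dim) + scatter)
    scale = (scale + scale.T) / 2
    return stats.wishart.rvs(df=df0 + n, scale=scale, random_state=rng)


def _gamma_precision(a0, b0, half_dof, half_ss, rng) -> float:
    return rng.gamma(a0 + half_dof, 1.0 / (b0 + half_ss))


def latent_z_conditional(w, resid, beta_expo, Qe, QU, QZ, mu_Z):
    """Mean and covariance of the normal full conditional of one latent exposure.

    ``resid`` is the record's response residual with the exposure contribution
    removed; ``beta_expo`` has shape (P, K). Combines three precisions: the
    outcome likelihood (beta' Qe beta), the proxy W (QU) and the structural
    exposure model (QZ). With ``beta_expo = 0``, ``mu_Z = 0`` and equal
    proxy/structural precisions the mean reduces to W/2.
    """
    G = np.atleast_2d(np.asarray(beta_expo, dtype=float))
    Qe = np.atleast_2d(Qe)
    QU = np.atleast_2d(QU)
    QZ = np.atleast_2d(QZ)
    w = np.atleast_1d(np.asarray(w, dtype=float))
    resid = np.atleast_1d(np.asarray(resid, dtype=float))
    mu_Z = np.atleast_1d(np.asarray(mu_Z, dtype=float))
    M = G @ Qe @ G.T + QU + QZ
    b = G @ Qe @ resid + QU @ w + QZ @ mu_Z
    cov = np.linalg.inv(M)
    return cov @ b, cov


# ---------------------------------------------------------------------------
# design construction

class _Design:
    __slots__ = (
        "y", "X", "W", "subj", "cell", "site", "x_names", "n", "K", "P",
        "y_center", "y_scale", "x_center", "x_scale", "w_center", "w_scale",
        "subj_counts", "cell_counts", "site_counts",
        "n_subjects", "n_cells", "n_sites",
    )


def _build_design(data: CrossoverDataset, spec: ModelSpec) -> _Design:
    rec = data.records
    missing = [f for f in spec.feature_ids if f not in data.omics.index]
    if missing:
        raise KeyError(f"features not in dataset: {missing}")
    for pol in spec.pollutant_ids:
        if f"W_{pol}" not in rec.columns:
            raise KeyError(f"pollutant {pol!r} not in dataset")

    d = _Design()
    d.y = data.omics.loc[spec.feature_ids].to_numpy(float).T  # (n, K)
    d.W = rec[[f"W_{p}" for p in spec.pollutant_ids]].to_numpy(float)
    d.n, d.K = d.y.shape
    d.P = d.W.shape[1]

    cols, names, is_cont = [], [], []
    names.append("intercept"); cols.append(np.ones(d.n)); is_cont.append(False)
    if "sex" in spec.covariates:
        names.append("sex"); cols.append(rec["sex"].to_numpy(float)); is_cont.append(False)
    if "age" in spec.covariates:
        names.append("age"); cols.append(rec["age"].to_numpy(float)); is_cont.append(True)
    if "bmi" in spec.covariates:
        names.append("bmi"); cols.append(rec["bmi"].to_numpy(float)); is_cont.append(True)
    if "group" in spec.covariates:
        for g in ("COPD", "IHD"):
            names.append(f"grp_{g}")
            cols.append((rec["group"] == g).to_numpy(float))
            is_cont.append(False)
    if "annual" in spec.covariates:
        for pol in spec.pollutant_ids:
            names.append(f"annual_{pol}")
            cols.append(rec[f"annual_{pol}"].to_numpy(float))
            is_cont.append(True)
    X = np.column_stack(cols)

    # drop degenerate (constant) columns, keeping the intercept
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0.0:
            warnings.warn(f"dropping constant design column {names[j]!r}", UserWarning)
        else:
            keep.append(j)
    X = X[:, keep]
    names = [names[j] for j in keep]
    is_cont = [is_cont[j] for j in keep]

    d.x_center = np.zeros(X.shape[1])
    d.x_scale = np.ones(X.shape[1])
    d.y_center = np.zeros(d.K); d.y_scale = np.ones(d.K)
    d.w_center = np.zeros(d.P); d.w_scale = np.ones(d.P)
    if spec.standardize:
        for j, cont in enumerate(is_cont):
            if cont:
                d.x_center[j] = X[:, j].mean()
                d.x_scale[j] = X[:, j].std() or 1.0
        X = (X - d.x_center) / d.x_scale
        d.y_center = d.y.mean(axis=0)
        d.y_scale = np.where(d.y.std(axis=0) > 0, d.y.std(axis=0), 1.0)
        d.y = (d.y - d.y_center) / d.y_scale
        d.w_center = d.W.mean(axis=0)
        d.w_scale = np.where(d.W.std(axis=0) > 0, d.W.std(axis=0), 1.0)
        d.W = (d.W - d.w_center) / d.w_scale
    d.X = X
    d.x_names = names

    D0 = np.concatenate([X, d.W], axis=1)
    if np.linalg.matrix_rank(D0) < D0.shape[1]:
        raise ValueError("rank-deficient design matrix (covariates + exposures)")

    d.subj = pd.factorize(rec["subject_id"])[0]
    labels = rec["site"].astype(str) + "_" + rec["timepoint"].astype(str)
    d.cell = labels.map({c: i for i, c in enumerate(CELLS)}).to_numpy()
    d.site = pd.factorize(rec["site"])[0]
    d.n_subjects = int(d.subj.max()) + 1
    d.n_cells = int(d.cell.max()) + 1
    d.n_sites = int(d.site.max()) + 1
    d.subj_counts = np.bincount(d.subj, minlength=d.n_subjects)
    d.cell_counts = np.bincount(d.cell, minlength=d.n_cells)
    d.site_counts = np.bincount(d.site, minlength=d.n_sites)
    return d


def _std_error_variance(priors: PriorConfig, P: int, w_scale: np.ndarray):
    """Fixed measurement-error (co)variance mapped to the standardized W scale."""
    ev = priors.error_variance
    if ev is None:
        return None
    if np.isscalar(ev) or np.ndim(ev) == 0:
        mat = np.eye(P) * float(ev)
    else:
        mat = np.asarray(ev, dtype=float)
        if mat.shape != (P, P):
            raise ValueError(f"error_variance shape {mat.shape} != ({P}, {P})")
    inv_s = 1.0 / w_scale
    return mat * np.outer(inv_s, inv_s)


# ---------------------------------------------------------------------------
# one chain

def _update_group_effects(resid, idx, n_levels, counts, Qe, prior_var, rng, K):
    sums = np.zeros((n_levels, K))
    np.add.at(sums, idx, resid)
    out = np.empty((n_levels, K))
    for c in np.unique(counts):
        sel = counts == c
        prec = c * Qe + np.eye(K) / prior_var
        out[sel] = _draw_mvn_prec_many(prec, sums[sel] @ Qe, rng)
    return out


def _run_chain(d: _Design, priors: PriorConfig, *, corrected: bool,
               sigma_u_std, include_re: bool, n_iter: int, burnin: int,
               thin: int, rng) -> dict:
    n, K, P, p = d.n, d.K, d.P, d.X.shape[1]
    q = p + P
    y, X, W, subj, cell = d.y, d.X, d.W, d.subj, d.cell
    S, C = d.n_subjects, d.n_cells

    v0 = priors.coef_prior_variance
    a0, b0 = priors.precision_shape, priors.precision_rate
    wdf_K = priors.wishart_df if priors.wishart_df is not None else K
    wdf_P = priors.wishart_df if priors.wishart_df is not None else P
    wrate = priors.wishart_scale_diag

    fixed_e = priors.noise_variance
    fixed_e_std = None
    if fixed_e is not None:
        if K != 1:
            raise ValueError("noise_variance can only be fixed for a single feature")
        fixed_e_std = float(fixed_e) / float(d.y_scale[0] ** 2)

    sample_u = corrected and sigma_u_std is None
    zero_u = corrected and sigma_u_std is not None and np.allclose(sigma_u_std, 0.0)

    # state
    theta = rng.normal(0.0, 0.3, size=(q, K))
    gamma = np.zeros((S, K))
    delta = np.zeros((C, K))
    sig_g2 = 1.0
    sig_d2 = 1.0
    Qe = np.eye(K) if fixed_e_std is None else np.eye(K) / fixed_e_std
    Z = W.copy()
    D = np.concatenate([X, Z], axis=1)
    DtD = D.T @ D  # recomputed when Z moves
    site = d.site
    n_sites = d.n_sites
    if corrected:
        mu_Z = np.stack([Z[site == s].mean(axis=0) for s in range(n_sites)])
        QZ = np.linalg.inv(np.cov(Z.T).reshape(P, P) + 1e-8 * np.eye(P))
        if sample_u:
            QU = np.eye(P)
        elif zero_u:
            QU = None
        else:
            QU = np.linalg.inv(np.asarray(sigma_u_std, dtype=float))

    n_ret = (n_iter - burnin + thin - 1) // thin
    out = {
        "theta": np.empty((n_ret, q, K)),
        "sigma_gamma2": np.empty(n_ret),
        "sigma_delta2": np.empty(n_ret),
        "gamma": np.empty((n_ret, S, K)),
        "delta": np.empty((n_ret, C, K)),
    }
    if K == 1:
        out["sigma_e2"] = np.empty(n_ret)
    else:
        out["Sigma_e"] = np.empty((n_ret, K, K))
    if corrected:
        out["mu_Z"] = np.empty((n_ret, n_sites, P))
        out["Sigma_Z"] = np.empty((n_ret, P, P))
        if sample_u:
            out["Sigma_U"] = np.empty((n_ret, P, P))
        z_sum = np.zeros((n, P))
        z_sumsq = np.zeros((n, P))

    eye_qK = np.eye(q * K)
    kept = 0
    for it in range(n_iter):
        # --- joint fixed-effect + exposure-coefficient block
        R = y - gamma[subj] - delta[cell]
        if K == 1:
            prec = DtD * Qe[0, 0] + np.eye(q) / v0
            b = (D.T @ R[:, 0]) * Qe[0, 0]
            theta = _draw_mvn_prec(prec, b, rng)[:, None]
        else:
            prec = np.kron(Qe, DtD) + eye_qK / v0
            b = (D.T @ R @ Qe).ravel(order="F")
            theta = _draw_mvn_prec(prec, b, rng).reshape(q, K, order="F")
        fitted = D @ theta

        # --- random effects
        if include_re:
            R2 = y - fitted - delta[cell]
            gamma = _update_group_effects(R2, subj, S, d.subj_counts, Qe, sig_g2, rng, K)
            R3 = y - fitted - gamma[subj]
            delta = _update_group_effects(R3, cell, C, d.cell_counts, Qe, sig_d2, rng, K)
            sig_g2 = 1.0 / _gamma_precision(a0, b0, S * K / 2, 0.5 * np.sum(gamma**2), rng)
            sig_d2 = 1.0 / _gamma_precision(a0, b0, C * K / 2, 0.5 * np.sum(delta**2), rng)

        # --- residual (co)variance
        E = y - fitted - gamma[subj] - delta[cell]
        if fixed_e_std is None:
            if K == 1:
                prec_e = _gamma_precision(a0, b0, n / 2, 0.5 * np.sum(E**2), rng)
                Qe = np.array([[prec_e]])
            else:
                Qe = _wishart_precision(wdf_K, wrate, E.T @ E, n, rng)

        # --- measurement-error layer
        if corrected:
            G = theta[p:, :]  # (P, K)
            Rz = y - X @ theta[:p] - gamma[subj] - delta[cell]
            if zero_u:
                Z = W  # proxy is exact; latent exposure degenerates to W
            else:
                GQ = G @ Qe
                M = GQ @ G.T + QU + QZ
                B = Rz @ GQ.T + W @ QU + mu_Z[site] @ QZ
                Z = _draw_mvn_prec_many(M, B, rng)
            D[:, p:] = Z
            DtD = D.T @ D
            # site-specific latent-exposure means (crossover design)
            for s in range(n_sites):
                prec_mu = d.site_counts[s] * QZ + np.eye(P) / v0
                mu_Z[s] = _draw_mvn_prec(prec_mu, QZ @ Z[site == s].sum(axis=0), rng)
            Zc = Z - mu_Z[site]
            if P == 1:
                QZ = np.array([[_gamma_precision(a0, b0, n / 2, 0.5 * np.sum(Zc**2), rng)]])
            else:
                QZ = _wishart_precision(wdf_P, wrate, Zc.T @ Zc, n, rng)
            if sample_u:
                U = W - Z
                if P == 1:
                    QU = np.array([[_gamma_precision(a0, b0, n / 2, 0.5 * np.sum(U**2), rng)]])
                else:
                    QU = _wishart_precision(wdf_P, wrate, U.T @ U, n, rng)

        # --- store
        if it >= burnin and (it - burnin) % thin == 0:
            out["theta"][kept] = theta
            out["sigma_gamma2"][kept] = sig_g2
            out["sigma_delta2"][kept] = sig_d2
            out["gamma"][kept] = gamma
            out["delta"][kept] = delta
            if K == 1:
                out["sigma_e2"][kept] = fixed_e_std if fixed_e_std is not None else 1.0 / Qe[0, 0]
            else:
                out["Sigma_e"][kept] = np.linalg.inv(Qe)
            if corrected:
                out["mu_Z"][kept] = mu_Z
                out["Sigma_Z"][kept] = np.linalg.inv(QZ)
                if sample_u:
                    out["Sigma_U"][kept] = np.linalg.inv(QU)
                z_sum += Z
                z_sumsq += Z**2
            kept += 1

    if corrected:
        out["z_mean"] = z_sum / max(kept, 1)
        out["z_sd"] = np.sqrt(np.maximum(z_sumsq / max(kept, 1) - out["z_mean"] ** 2, 0.0))
    return out


# ---------------------------------------------------------------------------
# assembly and public fit functions

def _assemble(chain_outs: list[dict], d: _Design, spec: ModelSpec,
              mcmc: MCMCConfig, warnings_list: list[str]) -> PosteriorDraws:
    C = len(chain_outs)
    p = len(d.x_names)
    sy, sw = d.y_scale, d.w_scale
    cy, cw = d.y_center, d.w_center
    sx, cx = d.x_scale, d.x_center

    theta = np.stack([o["theta"] for o in chain_outs])  # (C, T, q, K)
    beta_all = theta[:, :, :p, :]        # std scale, incl. intercept
    bexpo_std = theta[:, :, p:, :]       # (C, T, P, K)

    params: dict[str, np.ndarray] = {}
    # exposure coefficients back to original units
    params["beta_expo"] = bexpo_std * (sy[None, None, None, :] / sw[None, None, :, None])
    params["beta_expo_std"] = bexpo_std
    # covariate coefficients (original units) and intercept
    bcov_std = beta_all[:, :, 1:, :]
    params["beta_cov"] = bcov_std * (sy[None, None, None, :] / sx[None, None, 1:, None])
    alpha_std = beta_all[:, :, 0, :]
    shift_x = np.einsum("ctjk,j->ctk", bcov_std, cx[1:] / sx[1:])
    shift_w = np.einsum("ctjk,j->ctk", bexpo_std, cw / sw)
    params["alpha"] = cy[None, None, :] + sy[None, None, :] * (alpha_std - shift_x - shift_w)
    # random effects (standardized-response scale) and their variances
    params["gamma"] = np.stack([o["gamma"] for o in chain_outs])
    params["delta"] = np.stack([o["delta"] for o in chain_outs])
    params["sigma_gamma2"] = np.stack([o["sigma_gamma2"] for o in chain_outs])
    params["sigma_delta2"] = np.stack([o["sigma_delta2"] for o in chain_outs])
    if d.K == 1:
        params["sigma_e2"] = np.stack([o["sigma_e2"] for o in chain_outs]) * sy[0] ** 2
    else:
        Se = np.stack([o["Sigma_e"] for o in chain_outs])
        params["Sigma_e"] = Se * np.outer(sy, sy)[None, None, :, :]
    if spec.corrected:
        params["mu_Z"] = np.stack([o["mu_Z"] for o in chain_outs]) * sw + cw
        sww = np.outer(sw, sw)[None, None, :, :]
        params["Sigma_Z"] = np.stack([o["Sigma_Z"] for o in chain_outs]) * sww
        if "Sigma_U" in chain_outs[0]:
            params["Sigma_U"] = np.stack([o["Sigma_U"] for o in chain_outs]) * sww
        params["z_mean"] = np.stack([o["z_mean"] for o in chain_outs]) * sw + cw
        params["z_sd"] = np.stack([o["z_sd"] for o in chain_outs]) * sw

    _check_draw_invariants(params)
    return PosteriorDraws(
        params=params,
        spec=spec,
        mcmc=mcmc,
        feature_ids=list(spec.feature_ids),
        pollutant_ids=list(spec.pollutant_ids),
        covariate_names=list(d.x_names[1:]),
        scales={
            "y_center": cy, "y_scale": sy, "w_center": cw, "w_scale": sw,
            "note": "gamma/delta blocks and their variances are on the "
                    "standardized-response scale",
        },
        warnings=warnings_list,
    )


def _check_draw_invariants(params: dict[str, np.ndarray]) -> None:
    """Every retained variance draw positive; covariance draws symmetric PD."""
    for key in ("sigma_e2", "sigma_gamma2", "sigma_delta2"):
        if key in params and not np.all(params[key] > 0):
            raise RuntimeError(f"non-positive {key} draw")
    for key in ("Sigma_e", "Sigma_Z", "Sigma_U"):
        if key in params:
            arr = params[key]
            if not np.allclose(arr, np.swapaxes(arr, -1, -2), atol=1e-8):
                raise RuntimeError(f"asymmetric {key} draw")
            try:
                np.linalg.cholesky(arr)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(f"non-PD {key} draw") from exc


def fit(data: CrossoverDataset, spec: ModelSpec, mcmc: MCMCConfig | None = None) -> PosteriorDraws:
    """Fit any model variant by blocked Gibbs sampling.

    Chains are run sequentially with independent sub-seeds spawned from
    ``mcmc.seed``; identical configuration and seed reproduce the draws
    bit-for-bit.
    """
    mcmc = mcmc or MCMCConfig()
    spec.validate()
    mcmc.validate()
    d = _build_design(data, spec)
    if d.K >= 2 and d.n <= d.K:
        raise ValueError(
            f"{d.K} features with only {d.n} records: the default Wishart prior "
            "needs more records than features — reduce feature_ids or supply "
            "informative priors"
        )
    warn_list: list[str] = []
    sigma_u_std = None
    if spec.corrected:
        sigma_u_std = _std_error_variance(spec.priors, d.P, d.w_scale)
        if sigma_u_std is None:
            msg = (
                "error variance is sampled without replicate measurements: "
                "sigma_U^2 is only weakly identified; fit proceeds"
            )
            warnings.warn(msg, UserWarning)
            warn_list.append(msg)

    ss = np.random.SeedSequence(mcmc.seed)
    chain_outs = []
    for child in ss.spawn(mcmc.n_chains):
        rng = np.random.default_rng(child)
        chain_outs.append(
            _run_chain(
                d, spec.priors, corrected=spec.corrected, sigma_u_std=sigma_u_std,
                include_re=spec.include_random_effects, n_iter=mcmc.n_iter,
                burnin=mcmc.n_burnin, thin=mcmc.thin, rng=rng,
            )
        )
    return _assemble(chain_outs, d, spec, mcmc, warn_list)


def fit_univariate(data, spec, mcmc=None) -> PosteriorDraws:
    """Naive single-feature, single-pollutant mixed model (proxy W used as-is)."""
    if spec.variant != "naive_uni":
        raise ValueError("fit_univariate requires variant 'naive_uni'")
    return fit(data, spec, mcmc)


def fit_corrected_univariate(data, spec, mcmc=None) -> PosteriorDraws:
    """Error-corrected single-feature model with a latent true-exposure block."""
    if spec.variant != "corrected_uni":
        raise ValueError("fit_corrected_univariate requires variant 'corrected_uni'")
    return fit(data, spec, mcmc)


def fit_multiomics(data, spec, mcmc=None) -> PosteriorDraws:
    """Multivariate-response model: features share a residual covariance Sigma_e."""
    if not spec.variant.endswith("multiomics"):
        raise ValueError("fit_multiomics requires a multiomics variant")
    return fit(data, spec, mcmc)


def fit_multiexposure(data, spec, mcmc=None) -> PosteriorDraws:
    """Multivariate-exposure model: pollutants enter jointly, with Wishart priors
    on the exposure covariance (and error covariance when sampled)."""
    if not spec.variant.endswith("multiexpo"):
        raise ValueError("fit_multiexposure requires a multiexpo variant")
    return fit(data, spec, mcmc)


# ---------------------------------------------------------------------------
# vectorized batch of independent naive univariate fits (screening scale)

@dataclass
class BatchUnivariateDraws:
    """Retained exposure-coefficient draws of many independent naive univariate
    fits sharing one design (one pollutant, many features)."""

    beta_expo: np.ndarray  # (n_chains, n_retained, n_features), original scale
    feature_ids: list[str]
    pollutant_id: str
    variant: str = "naive_uni"
    mcmc: MCMCConfig | None = None

    def draws_for(self, feature: str) -> np.ndarray:
        j = self.feature_ids.index(feature)
        return self.beta_expo[:, :, j].ravel()


def fit_univariate_batch(
    data: CrossoverDataset,
    feature_ids: list[str],
    pollutant: str,
    mcmc: MCMCConfig | None = None,
    priors: PriorConfig | None = None,
    standardize: bool = True,
) -> BatchUnivariateDraws:
    """Fit the naive univariate model independently for many features at once.

    Statistically identical to looping :func:`fit_univariate` over features
    (each feature has its own coefficients, random effects and variances), but
    the sweeps are vectorized across features, which is what makes
    metabolome-scale screening runs tractable.
    """
    mcmc = mcmc or MCMCConfig()
    mcmc.validate()
    priors = priors or PriorConfig()
    spec = ModelSpec(
        variant="naive_uni", feature_ids=[feature_ids[0]], pollutant_ids=[pollutant],
        priors=priors, standardize=standardize,
    )
    d = _build_design(data, spec)
    Y = data.omics.loc[feature_ids].to_numpy(float).T  # (n, F)
    y_center = Y.mean(axis=0) if standardize else np.zeros(Y.shape[1])
    y_scale = np.where(Y.std(axis=0) > 0, Y.std(axis=0), 1.0) if standardize else np.ones(Y.shape[1])
    Y = (Y - y_center) / y_scale

    D = np.concatenate([d.X, d.W], axis=1)
    n, F = Y.shape
    q = D.shape[1]
    DtD = D.T @ D
    subj, cell = d.subj, d.cell
    S, C = d.n_subjects, d.n_cells
    cnt_s = d.subj_counts[:, None]
    cnt_c = d.cell_counts[:, None]
    v0 = priors.coef_prior_variance
    a0, b0 = priors.precision_shape, priors.precision_rate

    ss = np.random.SeedSequence(mcmc.seed)
    n_ret = mcmc.n_retained
    bexpo = np.empty((mcmc.n_chains, n_ret, F))
    for ci, child in enumerate(ss.spawn(mcmc.n_chains)):
        rng = np.random.default_rng(child)
        theta = rng.normal(0.0, 0.3, size=(q, F))
        gamma = np.zeros((S, F))
        delta = np.zeros((C, F))
        prec_e = np.ones(F)
        sig_g2 = np.ones(F)
        sig_d2 = np.ones(F)
        kept = 0
        for it in range(mcmc.n_iter):
            R = Y - gamma[subj] - delta[cell]
            b = (D.T @ R) * prec_e  # (q, F)
            prec = prec_e[:, None, None] * DtD[None] + np.eye(q)[None] / v0
            cov = np.linalg.inv(prec)  # (F, q, q)
            mean = np.einsum("fij,jf->fi", cov, b)
            L = np.linalg.cholesky(cov)
            draw = mean + np.einsum("fij,fj->fi", L, rng.standard_normal((F, q)))
            theta = draw.T
            fitted = D @ theta
            # subject intercepts
            R2 = Y - fitted - delta[cell]
            sums = np.zeros((S, F)); np.add.at(sums, subj, R2)
            var = 1.0 / (cnt_s * prec_e[None, :] + 1.0 / sig_g2[None, :])
            gamma = var * sums * prec_e[None, :] + np.sqrt(var) * rng.standard_normal((S, F))
            # cell intercepts
            R3 = Y - fitted - gamma[subj]
            sums = np.zeros((C, F)); np.add.at(sums, cell, R3)
            var = 1.0 / (cnt_c * prec_e[None, :] + 1.0 / sig_d2[None, :])
            delta = var * sums * prec_e[None, :] + np.sqrt(var) * rng.standard_normal((C, F))
            sig_g2 = 1.0 / rng.gamma(a0 + S / 2, 1.0 / (b0 + 0.5 * np.sum(gamma**2, axis=0)))
            sig_d2 = 1.0 / rng.gamma(a0 + C / 2, 1.0 / (b0 + 0.5 * np.sum(delta**2, axis=0)))
            E = Y - fitted - gamma[subj] - delta[cell]
            prec_e = rng.gamma(a0 + n / 2, 1.0 / (b0 + 0.5 * np.sum(E**2, axis=0)))
            if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
                bexpo[ci, kept] = theta[-1]
                kept += 1

    bexpo = bexpo * (y_scale[None, None, :] / d.w_scale[0])
    return BatchUnivariateDraws(
        beta_expo=bexpo, feature_ids=list(feature_ids), pollutant_id=pollutant, mcmc=mcmc
    )
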