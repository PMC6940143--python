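"""Closed-form references: attenuation factors, OLS, conjugate linear-model posteriors.

These are the independent yardsticks the test suite holds the Gibbs samplers
against. Under classical measurement error ``W = Z + U`` the naive regression
of an outcome on ``W`` estimates ``lambda * beta`` with attenuation factor
``lambda = sigma_Z^2 / (sigma_Z^2 + sigma_U^2)``; the multivariate analogue is
``Lambda = Sigma_Z (Sigma_Z + Sigma_U)^{-1}``, and the expected naive
coefficient vector is ``Lambda' beta`` (bias of a null coefficient can be away
from zero when exposures are correlated).
"""

from __future__ import annotations

import numpy as np


def attenuation_factor(sigma_z2, sigma_u2):
    """Attenuation factor lambda (scalar) or matrix Lambda = Sigma_Z (Sigma_Z+Sigma_U)^-1.

    For the matrix case the expected naive coefficient vector is
    ``Lambda.T @ beta`` (equal to ``Lambda @ beta`` for the symmetric product
    of two symmetric matrices only when they commute).
    """
    if np.ndim(sigma_z2) == 0:
        sz, su = float(sigma_z2), float(sigma_u2)
        if sz <= 0:
            raise ValueError("sigma_z2 must be positive")
        if su < 0:
            raise ValueError("sigma_u2 must be non-negative")
        return sz / (sz + su)
    Sz = np.asarray(sigma_z2, dtype=float)
    Su = np.asarray(sigma_u2, dtype=float)
    if not (np.allclose(Sz, Sz.T) and np.allclose(Su, Su.T)):
        raise ValueError("covariance matrices must be symmetric")
    total = Sz + Su
    if np.linalg.matrix_rank(total) < total.shape[0]:
        raise np.linalg.LinAlgError("Sigma_Z + Sigma_U is singular")
    return Sz @ np.linalg.inv(total)


def ols_oracle(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact least squares: returns (coefficients, residual variance).

    Residual variance uses the 1/(n - p) denominator. Raises on rank
    deficiency.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(n - p, 1)
    return beta, float(resid @ resid / dof)


def conjugate_posterior_oracle(
    y: np.ndarray,
    X: np.ndarray,
    coef_prior_variance: float = 1000.0,
    noise_variance: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact normal posterior for linear regression with known noise variance.

    Independent N(0, coef_prior_variance) priors on each coefficient; returns
    (posterior mean, posterior covariance). With no data the posterior equals
    the prior; with ``coef_prior_variance = inf`` it reduces to OLS.
    """
    if noise_variance <= 0:
        raise ValueError("noise_variance must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size and X.shape[1] == y.size:
        X = X.T
    p = X.shape[1]
    prior_prec = 0.0 if np.isinf(coef_prior_variance) else 1.0 / coef_prior_variance
    if y.size == 0:
        if prior_prec == 0.0:
            raise ValueError("no data and an improper prior: posterior undefined")
        return np.zeros(p), np.eye(p) * coef_prior_variance
    prec = X.T @ X / noise_variance + np.eye(p) * prior_prec
    cov = np.linalg.inv(prec)
    cov = (cov + cov.T) / 2
    mean = cov @ (X.T @ y) / noise_variance
    return mean, cov
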