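"""Model/MCMC configuration types and the posterior-draw container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

VARIANTS = (
    "naive_uni",
    "corrected_uni",
    "naive_multiomics",
    "corrected_multiomics",
    "naive_multiexpo",
    "corrected_multiexpo",
)

DEFAULT_COVARIATES = ("sex", "age", "bmi", "group", "annual")


@dataclass
class PriorConfig:
    """Prior hyperparameters shared by all model variants.

    ``coef_prior_variance``: variance of the zero-mean normal priors on every
    regression coefficient (vague at 1000 on standardized data).
    ``precision_shape/rate``: Gamma(shape, rate) prior on every scalar
    precision (residual, random effects, exposure, error).
    ``wishart_df/wishart_scale_diag``: Wishart prior on precision matrices in
    the JAGS ``dwish(R, k)`` convention — density carries
    ``exp(-tr(R Q)/2)`` with ``R = wishart_scale_diag * I`` and ``k`` the
    degrees of freedom (defaults to the matrix dimension).
    ``error_variance``: measurement-error variance sigma_U^2 (scalar) or
    Sigma_U (matrix). ``None`` means "sample it under the gamma/Wishart
    prior"; a value fixes it (the identifiable choice when no replicate
    measurements exist).
    ``noise_variance``: if set, fixes the residual variance sigma_e^2 instead
    of sampling it (used for exact conjugate cross-checks).
    """

    coef_prior_variance: float = 1000.0
    precision_shape: float = 0.01
    precision_rate: float = 0.01
    wishart_df: float | None = None
    wishart_scale_diag: float = 0.01
    error_variance: float | np.ndarray | None = None
    noise_variance: float | None = None

    def validate(self, dim: int = 1) -> None:
        if self.coef_prior_variance <= 0:
            raise ValueError("coef_prior_variance must be positive")
        if self.precision_shape <= 0 or self.precision_rate <= 0:
            raise ValueError("gamma prior shape/rate must be positive")
        if self.wishart_scale_diag <= 0:
            raise ValueError("wishart_scale_diag must be positive")
        if self.wishart_df is not None and self.wishart_df < dim:
            raise ValueError(f"wishart_df must be >= matrix dimension ({dim})")


@dataclass
class ModelSpec:
    """Which model variant to fit, on which features/pollutants, with which priors."""

    variant: str
    feature_ids: list[str]
    pollutant_ids: list[str]
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    priors: PriorConfig = field(default_factory=PriorConfig)
    standardize: bool = True
    include_random_effects: bool = True

    @property
    def corrected(self) -> bool:
        return self.variant.startswith("corrected")

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        K, P = len(self.feature_ids), len(self.pollutant_ids)
        if self.variant.endswith("_uni") and (K != 1 or P != 1):
            raise ValueError("uni variants take exactly one feature and one pollutant")
        if self.variant.endswith("multiomics") and P != 1:
            raise ValueError("multiomics variants take exactly one pollutant")
        if K < 1 or P < 1:
            raise ValueError("need at least one feature and one pollutant")
        self.priors.validate(dim=max(K, P))


@dataclass
class MCMCConfig:
    n_chains: int = 4
    n_iter: int = 5000
    n_burnin: int = 2000
    thin: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burnin + self.thin - 1) // self.thin


@dataclass
class PosteriorDraws:
    """Retained MCMC draws for every parameter block.

    ``params`` maps block names to arrays with leading dimensions
    ``(n_chains, n_retained)``. Coefficient blocks (``alpha``, ``beta_cov``,
    ``beta_expo``) and variance blocks are stored on the original data scale;
    standardization book-keeping lives in ``scales``.
    """

    params: dict[str, np.ndarray]
    spec: ModelSpec
    mcmc: MCMCConfig
    feature_ids: list[str]
    pollutant_ids: list[str]
    covariate_names: list[str]
    scales: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: shape (n_chains * n_retained, ...)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def beta_expo_draws(self, feature=None, pollutant=None) -> np.ndarray:
        """Pooled draws of one exposure coefficient (original scale)."""
        f = 0 if feature is None else self.feature_ids.index(feature)
        p = 0 if pollutant is None else self.pollutant_ids.index(pollutant)
        return self.stacked("beta_expo")[:, p, f]

    def chains(self, name: str, index: tuple = ()) -> np.ndarray:
        """Per-chain draws of one scalar component: shape (n_chains, n_retained)."""
        arr = self.params[name]
        return arr[(slice(None), slice(None)) + index]
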