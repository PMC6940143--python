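"""Synthetic crossover-trial generator with known ground truth.

The generator emulates the statistical structure of a two-site, three-timepoint
randomized crossover trial of traffic-related air pollution (TRAP) and
metabolomic response: 60 subjects in three health groups of 20, four correlated
pollutants measured per record as an error-prone proxy ``W = Z + U`` (classical
additive error), and continuous omic features following a linear mixed model

    m_fr = alpha_f + beta_cov_f' x_r + beta_expo_f' z_r + gamma_f[subject]
           + delta_f[site x timepoint] + eps_fr

with a subject random intercept ``gamma`` (variance ``sigma_gamma2``), a
measurement-occasion random intercept ``delta`` shared across subjects
(variance ``sigma_delta2``), and residuals that are i.i.d. ``N(0, sigma_e2)``
or, when ``Sigma_e`` is given, correlated across features within a record.

Exposures are generated on a standardized (log-scale-like) scale: the models
downstream are linear, so the scale is free; street means exceed park means by
a configurable offset. Every random draw is reproducible from the config seed,
and the drawn true exposures, errors and coefficients are returned in a
:class:`~trapme.datatypes.SyntheticTruth` so recovery is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .datatypes import (
    CELLS,
    GROUPS,
    POLLUTANTS,
    SITES,
    TIMEPOINTS,
    CrossoverDataset,
    SyntheticTruth,
)

# Default cross-pollutant correlation: particulate matters track each other
# closely, black carbon tracks the PMs, NO2 shares the common traffic trend.
DEFAULT_SIGMA_Z = np.array(
    [
        [1.0, 0.5, 0.5, 0.5],
        [0.5, 1.0, 0.8, 0.7],
        [0.5, 0.8, 1.0, 0.7],
        [0.5, 0.7, 0.7, 1.0],
    ]
)

AGE_MEAN, AGE_SD = 60.0, 8.0
BMI_MEAN, BMI_SD = 27.0, 4.0


def _check_pd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} is not positive-definite") from exc
    return mat


@dataclass
class SimulationConfig:
    """Study-condition knobs of the generator; defaults mirror the trial design."""

    n_per_group: int = 20
    n_features: int = 10
    pollutants: tuple[str, ...] = POLLUTANTS
    site_mean_offset: float = 1.0        # street minus park, per pollutant
    Sigma_Z: np.ndarray | None = None    # default: DEFAULT_SIGMA_Z (subsetted)
    error_cov: float | np.ndarray = 1.0  # scalar sigma_U2 or full Sigma_U
    sigma_e2: float = 1.0
    Sigma_e: np.ndarray | None = None    # correlated residuals across features
    sigma_gamma2: float = 0.5
    sigma_delta2: float = 0.25
    beta_expo: np.ndarray | None = None  # (n_features, P); default: one active pair
    beta_cov: float | np.ndarray = 0.2
    alpha: float | np.ndarray = 0.0
    seed: int = 0

    def resolved_sigma_z(self) -> np.ndarray:
        if self.Sigma_Z is not None:
            return _check_pd(self.Sigma_Z, "Sigma_Z")
        idx = [POLLUTANTS.index(p) if p in POLLUTANTS else None for p in self.pollutants]
        if None in idx:
            return np.eye(len(self.pollutants))
        return DEFAULT_SIGMA_Z[np.ix_(idx, idx)]

    def resolved_beta_expo(self) -> np.ndarray:
        P = len(self.pollutants)
        if self.beta_expo is None:
            # one detectable association (first feature, first pollutant), rest null
            b = np.zeros((self.n_features, P))
            b[0, 0] = 0.5
            return b
        b = np.asarray(self.beta_expo, dtype=float)
        if b.shape != (self.n_features, P):
            raise ValueError(
                f"beta_expo has shape {b.shape}, expected {(self.n_features, P)}"
            )
        return b

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("Sigma_Z", "Sigma_e", "beta_expo", "error_cov", "beta_cov", "alpha"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = np.asarray(raw[key], dtype=float)
        if "pollutants" in raw:
            raw["pollutants"] = tuple(raw["pollutants"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = {}
        for k, v in asdict(self).items():
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, tuple):
                v = list(v)
            payload[k] = v
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def generate_subjects(n_per_group: int, seed: int = 0) -> pd.DataFrame:
    """Generate the subject table: three health groups, sex/age/BMI covariates.

    Sex is Bernoulli(0.5); age and BMI come from normals truncated at zero
    (means 60 y / 27 kg m^-2 — a mixed healthy/COPD/IHD adult cohort).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be a positive integer")
    rng = np.random.default_rng(seed)
    n = 3 * n_per_group
    ids = [f"S{i + 1:03d}" for i in range(n)]
    group = np.repeat(list(GROUPS), n_per_group)
    sex = rng.integers(0, 2, size=n)
    age = stats.truncnorm.rvs(
        (0 - AGE_MEAN) / AGE_SD, np.inf, loc=AGE_MEAN, scale=AGE_SD, size=n, random_state=rng
    )
    bmi = stats.truncnorm.rvs(
        (0 - BMI_MEAN) / BMI_SD, np.inf, loc=BMI_MEAN, scale=BMI_SD, size=n, random_state=rng
    )
    return pd.DataFrame(
        {"subject_id": ids, "group": group, "sex": sex, "age": age, "bmi": bmi}
    )


def generate_true_exposures(
    subjects: pd.DataFrame,
    site_means: dict[str, Sequence[float]] | None = None,
    Sigma_Z: np.ndarray | None = None,
    seed: int = 0,
    pollutants: Sequence[str] = POLLUTANTS,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw true exposures Z for every subject x site x timepoint record.

    Z is multivariate normal per record with a site-specific mean (street above
    park) and cross-pollutant covariance ``Sigma_Z``. A subject-level annual
    background exposure is drawn once per subject per pollutant.

    Returns ``(records, Z)`` where ``records`` is the long-format frame
    (without W columns) and ``Z`` the ``(n_records, P)`` exposure matrix.
    """
    P = len(pollutants)
    if Sigma_Z is None:
        Sigma_Z = np.eye(P)
    Sigma_Z = _check_pd(np.asarray(Sigma_Z, dtype=float), "Sigma_Z")
    if Sigma_Z.shape[0] != P:
        raise ValueError(f"Sigma_Z dimension {Sigma_Z.shape[0]} != {P} pollutants")
    if site_means is None:
        site_means = {"park": [-0.5] * P, "street": [0.5] * P}
    rng = np.random.default_rng(seed)

    rows = []
    for _, subj in subjects.iterrows():
        for site in SITES:
            for tp in TIMEPOINTS:
                rows.append(
                    {
                        "record_id": f"{subj.subject_id}_{site}_{tp}",
                        "subject_id": subj.subject_id,
                        "group": subj.group,
                        "sex": subj.sex,
                        "age": subj.age,
                        "bmi": subj.bmi,
                        "site": site,
                        "timepoint": tp,
                    }
                )
    records = pd.DataFrame(rows).set_index("record_id")

    L = np.linalg.cholesky(Sigma_Z)
    z = rng.standard_normal((len(records), P)) @ L.T
    means = np.array([site_means[s] for s in records["site"]], dtype=float)
    z = z + means

    annual = rng.standard_normal((len(subjects), P))
    annual_per_record = annual[pd.factorize(records["subject_id"])[0]]
    for j, pol in enumerate(pollutants):
        records[f"annual_{pol}"] = annual_per_record[:, j]
    return records, z


def contaminate(
    z: np.ndarray,
    error_cov: float | np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply classical additive error: W = Z + U with U ~ N(0, error_cov).

    ``error_cov`` may be a scalar variance (shared by all pollutants,
    independent errors) or a full symmetric PSD matrix. Returns ``(W, U)``.
    """
    z = np.asarray(z, dtype=float)
    n, P = z.shape
    rng = np.random.default_rng(seed)
    if np.isscalar(error_cov) or np.ndim(error_cov) == 0:
        s2 = float(error_cov)
        if s2 < 0:
            raise ValueError("scalar error_cov must be non-negative")
        u = rng.standard_normal((n, P)) * np.sqrt(s2)
    else:
        cov = np.asarray(error_cov, dtype=float)
        if cov.shape != (P, P):
            raise ValueError(f"error_cov shape {cov.shape} does not match {P} pollutants")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("error_cov must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10:
            raise ValueError("error_cov must be positive semi-definite")
        # eigh-based root handles singular (zero-error) directions
        vals, vecs = np.linalg.eigh(cov)
        root = vecs * np.sqrt(np.clip(vals, 0, None))
        u = rng.standard_normal((n, P)) @ root.T
    return z + u, u


def generate_omics(
    records: pd.DataFrame,
    z: np.ndarray,
    truth: SyntheticTruth,
    n_features: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the omic feature matrix from the mixed-model structure in `truth`.

    gamma is drawn once per subject (per feature), delta once per site x
    timepoint cell (shared across subjects), residuals independently per
    record — multivariate across features when ``truth.Sigma_e`` is set.
    """
    rng = np.random.default_rng(seed)
    F = n_features
    if truth.beta_expo.shape[0] != F:
        raise ValueError("truth.beta_expo rows inconsistent with n_features")
    X = covariate_matrix(records, truth)
    if truth.beta_cov.shape[1] != X.shape[1]:
        raise ValueError("truth.beta_cov columns inconsistent with covariates")

    subj_idx = pd.factorize(records["subject_id"])[0]
    cell_idx = (
        (records["site"].astype(str) + "_" + records["timepoint"].astype(str))
        .map({c: i for i, c in enumerate(CELLS)})
        .to_numpy()
    )
    S = subj_idx.max() + 1
    C = len(CELLS)

    gamma = rng.standard_normal((F, S)) * np.sqrt(truth.sigma_gamma2)
    delta = rng.standard_normal((F, C)) * np.sqrt(truth.sigma_delta2)
    n = len(records)
    if truth.Sigma_e is not None:
        Se = _check_pd(truth.Sigma_e, "Sigma_e")
        if Se.shape[0] != F:
            raise ValueError("Sigma_e dimension must equal n_features")
        eps = (rng.standard_normal((n, F)) @ np.linalg.cholesky(Se).T).T
    else:
        eps = rng.standard_normal((F, n)) * np.sqrt(truth.sigma_e2)

    mu = (
        truth.alpha[:, None]
        + truth.beta_cov @ X.T
        + truth.beta_expo @ z.T
        + gamma[:, subj_idx]
        + delta[:, cell_idx]
    )
    m = mu + eps
    feature_ids = [f"F{i + 1:04d}" for i in range(F)]
    return pd.DataFrame(m, index=feature_ids, columns=records.index)


def covariate_matrix(records: pd.DataFrame, truth: SyntheticTruth) -> np.ndarray:
    """Generative covariate design (standardized age/BMI, group dummies, annual)."""
    cols = []
    cols.append(records["sex"].to_numpy(float))
    cols.append((records["age"].to_numpy(float) - AGE_MEAN) / AGE_SD)
    cols.append((records["bmi"].to_numpy(float) - BMI_MEAN) / BMI_SD)
    cols.append((records["group"] == "COPD").to_numpy(float))
    cols.append((records["group"] == "IHD").to_numpy(float))
    for pol in truth.pollutants:
        cols.append(records[f"annual_{pol}"].to_numpy(float))
    return np.column_stack(cols)


def simulate_dataset(config: SimulationConfig) -> tuple[CrossoverDataset, SyntheticTruth]:
    """Generate a full dataset plus its hidden truth, deterministically from the seed."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    try:
        subjects = generate_subjects(config.n_per_group, seed=seeds[0])
    except ValueError as exc:
        raise ValueError(f"[subjects] {exc}") from exc

    P = len(config.pollutants)
    Sigma_Z = config.resolved_sigma_z()
    site_means = {
        "park": [-config.site_mean_offset / 2] * P,
        "street": [config.site_mean_offset / 2] * P,
    }
    try:
        records, z = generate_true_exposures(
            subjects, site_means, Sigma_Z, seed=seeds[1], pollutants=config.pollutants
        )
    except ValueError as exc:
        raise ValueError(f"[exposures] {exc}") from exc

    try:
        w, u = contaminate(z, config.error_cov, seed=seeds[2])
    except ValueError as exc:
        raise ValueError(f"[contaminate] {exc}") from exc
    for j, pol in enumerate(config.pollutants):
        records[f"W_{pol}"] = w[:, j]

    covariate_names = ("sex", "age_std", "bmi_std", "grp_COPD", "grp_IHD") + tuple(
        f"annual_{p}" for p in config.pollutants
    )
    beta_expo = config.resolved_beta_expo()
    beta_cov = config.beta_cov
    if np.isscalar(beta_cov):
        beta_cov = np.full((config.n_features, len(covariate_names)), float(beta_cov))
    alpha = config.alpha
    if np.isscalar(alpha):
        alpha = np.full(config.n_features, float(alpha))

    error_cov = config.error_cov
    if np.isscalar(error_cov) or np.ndim(error_cov) == 0:
        error_cov_mat = np.eye(P) * float(error_cov)
    else:
        error_cov_mat = np.asarray(error_cov, dtype=float)

    truth = SyntheticTruth(
        beta_expo=beta_expo,
        alpha=np.asarray(alpha, dtype=float),
        beta_cov=np.asarray(beta_cov, dtype=float),
        sigma_e2=config.sigma_e2,
        Sigma_e=None if config.Sigma_e is None else np.asarray(config.Sigma_e, float),
        sigma_gamma2=config.sigma_gamma2,
        sigma_delta2=config.sigma_delta2,
        Sigma_Z=Sigma_Z,
        error_cov=error_cov_mat,
        site_means={k: list(v) for k, v in site_means.items()},
        z=z,
        u=u,
        seed=config.seed,
        pollutants=tuple(config.pollutants),
        covariate_names=covariate_names,
        covariate_centers={"age": AGE_MEAN, "bmi": BMI_MEAN},
        covariate_scales={"age": AGE_SD, "bmi": BMI_SD},
    )
    truth.validate()

    try:
        omics = generate_omics(records, z, truth, config.n_features, seed=seeds[3])
    except ValueError as exc:
        raise ValueError(f"[omics] {exc}") from exc

    ds = CrossoverDataset(records=records, omics=omics)
    ds.validate()
    return ds, truth
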