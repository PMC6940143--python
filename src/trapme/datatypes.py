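"""Core data containers for the crossover-trial exposure/omics analysis.

The study design emulated throughout the package is a randomized crossover
trial: every subject walks at two sites (a traffic-free park and a busy
street) and gives blood at three timepoints per walk (before, +2 h, +24 h),
so a complete dataset carries exactly ``2 x 3 = 6`` records per subject.
Observed pollutant concentrations are error-prone proxies ``W = Z + U`` of
the true personal exposures ``Z``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

POLLUTANTS = ("NO2", "PM25", "PM10", "CBLK")
SITES = ("park", "street")
TIMEPOINTS = ("pre", "post2h", "post24h")
GROUPS = ("healthy", "COPD", "IHD")

#: site x timepoint cells, in canonical order (6 for the full design)
CELLS = tuple(f"{s}_{t}" for s in SITES for t in TIMEPOINTS)


class DatasetSchemaError(ValueError):
    """Raised when a dataset violates the documented long-format schema."""


def _as_matrix(x, name: str) -> np.ndarray | None:
    if x is None:
        return None
    return np.asarray(x, dtype=float)


@dataclass
class CrossoverDataset:
    """Long-format crossover-trial dataset.

    Attributes
    ----------
    records : pandas.DataFrame
        One row per subject x site x timepoint, indexed by ``record_id``.
        Columns: ``subject_id, group, sex, age, bmi, site, timepoint`` plus
        ``W_<pollutant>`` observed exposures and ``annual_<pollutant>``
        background exposures.
    omics : pandas.DataFrame
        Continuous omic feature values (log-scale intensities), one row per
        feature, columns aligned with ``records.index``.
    """

    records: pd.DataFrame
    omics: pd.DataFrame

    @property
    def pollutants(self) -> list[str]:
        return [c[2:] for c in self.records.columns if c.startswith("W_")]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.omics.index)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        """Check design completeness and value sanity; raise DatasetSchemaError."""
        rec = self.records
        required = {"subject_id", "group", "sex", "age", "bmi", "site", "timepoint"}
        missing = required - set(rec.columns)
        if missing:
            raise DatasetSchemaError(f"records missing columns: {sorted(missing)}")
        counts = rec.groupby("subject_id", sort=False).size()
        bad = counts[counts != len(CELLS)]
        if len(bad):
            raise DatasetSchemaError(
                "incomplete design: subject(s) "
                f"{list(bad.index)} have {list(bad.values)} records instead of {len(CELLS)}"
            )
        for col in ("age", "bmi"):
            vals = pd.to_numeric(rec[col], errors="coerce")
            if vals.isna().any():
                row = rec.index[vals.isna()][0]
                raise DatasetSchemaError(f"non-numeric {col} at record {row!r}")
            if (vals <= 0).any():
                row = rec.index[vals <= 0][0]
                raise DatasetSchemaError(f"non-positive {col} at record {row!r}")
        wcols = [c for c in rec.columns if c.startswith(("W_", "annual_"))]
        wvals = rec[wcols].apply(pd.to_numeric, errors="coerce")
        if wvals.isna().any().any():
            col = wvals.columns[wvals.isna().any()][0]
            row = wvals.index[wvals[col].isna()][0]
            raise DatasetSchemaError(f"non-numeric exposure value at ({row!r}, {col!r})")
        if not self.omics.columns.equals(rec.index):
            raise DatasetSchemaError("omics columns do not match record order")
        if self.omics.isna().any().any():
            raise DatasetSchemaError("omics matrix contains missing cells")

    def subject_index(self) -> np.ndarray:
        """Integer subject index per record (0..S-1, in order of appearance)."""
        return pd.factorize(self.records["subject_id"])[0]

    def cell_index(self) -> np.ndarray:
        """Integer site x timepoint cell index per record (canonical CELLS order)."""
        labels = self.records["site"].astype(str) + "_" + self.records["timepoint"].astype(str)
        return labels.map({c: i for i, c in enumerate(CELLS)}).to_numpy()


@dataclass
class SyntheticTruth:
    """Hidden generative state of a simulated dataset, for recovery tests.

    Arrays are aligned with the dataset's record order. ``z`` and ``u`` hold
    the true exposures and the drawn classical errors so that
    ``W = z + u`` exactly.
    """

    beta_expo: np.ndarray          # (n_features, n_pollutants)
    alpha: np.ndarray              # (n_features,)
    beta_cov: np.ndarray           # (n_features, n_covariates)
    sigma_e2: float
    Sigma_e: np.ndarray | None     # (K, K) residual covariance, or None (iid)
    sigma_gamma2: float
    sigma_delta2: float
    Sigma_Z: np.ndarray            # (P, P)
    error_cov: np.ndarray          # (P, P); diag(sigma_U2) in the scalar case
    site_means: dict[str, list[float]]
    z: np.ndarray                  # (n_records, P) true exposures
    u: np.ndarray                  # (n_records, P) classical errors
    seed: int
    pollutants: tuple[str, ...] = POLLUTANTS
    covariate_names: tuple[str, ...] = ()
    covariate_centers: dict[str, float] = field(default_factory=dict)
    covariate_scales: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("sigma_e2", "sigma_gamma2", "sigma_delta2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name, m in (("Sigma_Z", self.Sigma_Z), ("Sigma_e", self.Sigma_e)):
            if m is None:
                continue
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            try:
                np.linalg.cholesky(m)
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"{name} is not positive-definite") from exc

    def to_json(self, path) -> None:
        def enc(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        payload = {k: enc(v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        arrays = {"beta_expo", "alpha", "beta_cov", "Sigma_Z", "error_cov", "z", "u"}
        for k in arrays:
            payload[k] = np.asarray(payload[k], dtype=float)
        if payload.get("Sigma_e") is not None:
            payload["Sigma_e"] = np.asarray(payload["Sigma_e"], dtype=float)
        for k in ("pollutants", "covariate_names"):
            payload[k] = tuple(payload[k])
        return cls(**payload)
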