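"""Gibbs-engine tests: conjugacy, full conditionals, degeneracies, reproducibility.

Heavier statistical checks (attenuation recovery at full design scale, the
degeneracy chain at longer chains) live in test_acceptance.py; the tests here
use short chains and target structural correctness.
"""

import numpy as np
import pytest

from trapme import gibbs
from trapme.models import MCMCConfig, ModelSpec, PriorConfig
from trapme.oracles import attenuation_factor, conjugate_posterior_oracle
from trapme.synthetic import SimulationConfig, simulate_dataset

FAST = dict(n_chains=2, n_iter=800, n_burnin=300)


def _uni_spec(ds, **kw):
    return ModelSpec("naive_uni", [ds.feature_ids[0]], ["NO2"], **kw)


class TestConjugateEquivalence:
    def test_matches_closed_form_without_hierarchy(self):
        """With random effects off and sigma_e fixed, draws are i.i.d. from the
        exact normal posterior."""
        cfg = SimulationConfig(
            n_per_group=10, n_features=1, pollutants=("NO2",), Sigma_Z=np.eye(1),
            error_cov=0.0, sigma_gamma2=1e-12, sigma_delta2=1e-12,
            beta_expo=np.array([[1.0]]), seed=21,
        )
        ds, _ = simulate_dataset(cfg)
        spec = _uni_spec(
            ds, priors=PriorConfig(noise_variance=1.0),
            standardize=False, include_random_effects=False,
        )
        draws = gibbs.fit(ds, spec, MCMCConfig(n_chains=2, n_iter=3000, n_burnin=500, seed=1))
        d = gibbs._build_design(ds, spec)
        D = np.concatenate([d.X, d.W], axis=1)
        mean, cov = conjugate_posterior_oracle(d.y[:, 0], D, 1000.0, 1.0)
        b = draws.beta_expo_draws()
        assert b.mean() == pytest.approx(mean[-1], abs=4 * np.sqrt(cov[-1, -1] / b.size))
        assert b.std() == pytest.approx(np.sqrt(cov[-1, -1]), rel=0.05)


class TestLatentZConditional:
    def test_equal_precision_shrinkage(self):
        """beta=0, mu_Z=0, sigma_U^2=sigma_Z^2: conditional mean is W/2."""
        mean, cov = gibbs.latent_z_conditional(
            w=2.0, resid=0.3, beta_expo=0.0, Qe=1.0, QU=1.0, QZ=1.0, mu_Z=0.0
        )
        assert mean[0] == pytest.approx(1.0)
        assert cov[0, 0] == pytest.approx(0.5)

    def test_outcome_information_enters(self):
        m0, _ = gibbs.latent_z_conditional(1.0, 0.0, 1.0, 1.0, 1.0, 1.0, 0.0)
        m1, _ = gibbs.latent_z_conditional(1.0, 3.0, 1.0, 1.0, 1.0, 1.0, 0.0)
        assert m1[0] > m0[0]  # a large outcome residual pulls Z up when beta > 0


class TestNullCase:
    def test_null_effect_recovered(self, small_dataset):
        ds, _ = small_dataset
        # feature 2 has beta_expo = 0 in the generator's default pattern
        spec = ModelSpec("naive_uni", [ds.feature_ids[2]], ["NO2"])
        draws = gibbs.fit(ds, spec, MCMCConfig(seed=3, **FAST))
        b = draws.beta_expo_draws()
        lo, hi = np.quantile(b, [0.025, 0.975])
        assert abs(b.mean()) < 0.1
        assert lo < 0 < hi


class TestDegeneracies:
    def test_multiomics_k1_equals_univariate(self, uni_dataset):
        ds, _ = uni_dataset
        mc = MCMCConfig(seed=11, **FAST)
        a = gibbs.fit_univariate(ds, _uni_spec(ds), mc)
        b = gibbs.fit_multiomics(
            ds, ModelSpec("naive_multiomics", [ds.feature_ids[0]], ["NO2"]), mc
        )
        assert np.array_equal(a.params["beta_expo"], b.params["beta_expo"])

    def test_multiexpo_p1_equals_univariate(self, uni_dataset):
        ds, _ = uni_dataset
        mc = MCMCConfig(seed=11, **FAST)
        a = gibbs.fit_univariate(ds, _uni_spec(ds), mc)
        b = gibbs.fit_multiexposure(
            ds, ModelSpec("naive_multiexpo", [ds.feature_ids[0]], ["NO2"]), mc
        )
        assert np.array_equal(a.params["beta_expo"], b.params["beta_expo"])

    def test_corrected_zero_error_matches_naive(self, uni_dataset):
        ds, _ = uni_dataset
        a = gibbs.fit_univariate(ds, _uni_spec(ds), MCMCConfig(seed=12, **FAST))
        spec = ModelSpec("corrected_uni", [ds.feature_ids[0]], ["NO2"],
                         priors=PriorConfig(error_variance=0.0))
        b = gibbs.fit_corrected_univariate(ds, spec, MCMCConfig(seed=13, **FAST))
        assert b.beta_expo_draws().mean() == pytest.approx(
            a.beta_expo_draws().mean(), abs=0.05
        )


class TestAttenuationTracking:
    @pytest.mark.parametrize("sigma_u2", [0.5, 2.0])
    def test_naive_mean_tracks_lambda_beta(self, sigma_u2):
        cfg = SimulationConfig(
            n_per_group=20, n_features=1, pollutants=("NO2",), Sigma_Z=np.eye(1),
            error_cov=sigma_u2, beta_expo=np.array([[1.0]]), seed=31,
        )
        ds, _ = simulate_dataset(cfg)
        draws = gibbs.fit_univariate(ds, _uni_spec(ds), MCMCConfig(seed=32, **FAST))
        b = draws.beta_expo_draws()
        lam = attenuation_factor(1.0, sigma_u2)
        assert abs(b.mean() - lam) < 3 * b.std()

    def test_correlated_exposures_bias_null_coefficient(self):
        """Classical error with correlated exposures pushes the null pollutant's
        naive coefficient away from zero, as the matrix attenuation law predicts."""
        Sz = np.array([[1.0, 0.8], [0.8, 1.0]])
        cfg = SimulationConfig(
            n_per_group=20, n_features=1, pollutants=("NO2", "PM25"), Sigma_Z=Sz,
            error_cov=np.eye(2), beta_expo=np.array([[1.0, 0.0]]), seed=33,
        )
        ds, _ = simulate_dataset(cfg)
        draws = gibbs.fit_multiexposure(
            ds, ModelSpec("naive_multiexpo", [ds.feature_ids[0]], ["NO2", "PM25"]),
            MCMCConfig(seed=34, **FAST),
        )
        expected = attenuation_factor(Sz, np.eye(2)).T @ np.array([1.0, 0.0])
        got = draws.stacked("beta_expo")[:, :, 0].mean(axis=0)
        assert np.allclose(got, expected, atol=0.15)
        assert got[1] > 0.05  # genuinely biased away from zero


class TestInvariantsAndErrors:
    def test_seed_reproducibility(self, uni_dataset):
        ds, _ = uni_dataset
        mc = MCMCConfig(seed=5, n_chains=2, n_iter=400, n_burnin=100)
        a = gibbs.fit_univariate(ds, _uni_spec(ds), mc)
        b = gibbs.fit_univariate(ds, _uni_spec(ds), mc)
        for key in a.params:
            assert np.array_equal(a.params[key], b.params[key])

    def test_covariance_draws_symmetric_pd(self, small_dataset):
        ds, _ = small_dataset
        spec = ModelSpec("naive_multiomics", ds.feature_ids[:3], ["NO2"])
        draws = gibbs.fit_multiomics(ds, spec, MCMCConfig(seed=6, n_chains=1,
                                                          n_iter=400, n_burnin=100))
        Se = draws.stacked("Sigma_e")
        assert np.allclose(Se, np.swapaxes(Se, 1, 2))
        np.linalg.cholesky(Se)  # raises if any draw is not PD

    def test_too_many_features_refused(self):
        cfg = SimulationConfig(n_per_group=4, n_features=80, seed=1)
        tiny, _ = simulate_dataset(cfg)  # 72 records < 80 features
        spec = ModelSpec("naive_multiomics", tiny.feature_ids, ["NO2"])
        with pytest.raises(ValueError, match="more records than features"):
            gibbs.fit_multiomics(tiny, spec)

    def test_unknown_feature_rejected(self, small_dataset):
        ds, _ = small_dataset
        spec = ModelSpec("naive_uni", ["NOPE"], ["NO2"])
        with pytest.raises(KeyError, match="NOPE"):
            gibbs.fit(ds, spec)

    def test_sampled_error_variance_warns(self, uni_dataset):
        ds, _ = uni_dataset
        spec = ModelSpec("corrected_uni", [ds.feature_ids[0]], ["NO2"])  # no sigma_U given
        with pytest.warns(UserWarning, match="weakly identified"):
            draws = gibbs.fit(ds, spec, MCMCConfig(seed=8, n_chains=1,
                                                   n_iter=300, n_burnin=100))
        assert "Sigma_U" in draws.params

    def test_uni_variant_shape_validation(self, small_dataset):
        ds, _ = small_dataset
        spec = ModelSpec("naive_uni", ds.feature_ids[:2], ["NO2"])
        with pytest.raises(ValueError, match="exactly one feature"):
            gibbs.fit(ds, spec)


class TestBatchUnivariate:
    def test_batch_matches_single_fit_statistically(self, small_dataset):
        """The vectorized batch sampler and the single-feature sampler target the
        same posterior: means agree within combined Monte-Carlo error."""
        ds, _ = small_dataset
        mc = MCMCConfig(seed=9, n_chains=2, n_iter=1500, n_burnin=500)
        single = gibbs.fit_univariate(ds, _uni_spec(ds), mc)
        batch = gibbs.fit_univariate_batch(ds, ds.feature_ids, "NO2", mc)
        b_single = single.beta_expo_draws()
        b_batch = batch.draws_for(ds.feature_ids[0])
        tol = 4 * np.sqrt(b_single.var() / 200 + b_batch.var() / 200)
        assert b_batch.mean() == pytest.approx(b_single.mean(), abs=tol)
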