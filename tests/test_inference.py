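"""Decision-layer tests: Bayesian p-values, FDR rule, summaries, diagnostics, screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trapme import gibbs, inference
from trapme.models import MCMCConfig, ModelSpec
from trapme.synthetic import SimulationConfig, simulate_dataset


class TestBayesianPvalue:
    def test_one_sided_mass(self):
        assert inference.bayesian_pvalue(np.abs(np.random.default_rng(0).normal(5, 1, 500))) == 0.0

    def test_symmetric_null(self):
        draws = np.concatenate([np.ones(500), -np.ones(500)])
        assert inference.bayesian_pvalue(draws) == 1.0

    def test_proportion_arithmetic(self):
        draws = np.concatenate([np.ones(975), -np.ones(25)])
        assert inference.bayesian_pvalue(draws) == pytest.approx(0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            inference.bayesian_pvalue(np.array([]))

    @given(st.lists(st.floats(-10, 10), min_size=5, max_size=100), st.permutations(range(5)))
    def test_order_and_scale_invariance(self, vals, _perm):
        draws = np.asarray(vals)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(draws)
        assert inference.bayesian_pvalue(draws) == inference.bayesian_pvalue(shuffled)
        # strictly monotone sign-preserving rescaling
        assert inference.bayesian_pvalue(draws) == inference.bayesian_pvalue(
            np.sign(draws) * (np.abs(draws) ** 3 + np.abs(draws))
        )


class TestBayesianFdr:
    def test_hand_computed_running_means(self):
        # running means: 0.01, 0.015, 0.177 -> reject the first two
        rej = inference.bayesian_fdr([0.01, 0.02, 0.50], 0.05)
        assert rej.tolist() == [True, True, False]

    def test_all_zero_rejects_all(self):
        assert inference.bayesian_fdr(np.zeros(7), 0.05).all()

    def test_all_above_level_rejects_none(self):
        assert not inference.bayesian_fdr([0.06, 0.2, 0.9], 0.05).any()

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=50),
        st.floats(0.01, 0.5),
        st.floats(0.01, 0.4),
    )
    def test_monotone_in_level_and_order_invariant(self, vals, level, bump):
        p = np.asarray(vals)
        r1 = inference.bayesian_fdr(p, level)
        r2 = inference.bayesian_fdr(p, min(level + bump, 0.99))
        assert r2.sum() >= r1.sum()
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(p))
        assert inference.bayesian_fdr(p[perm], level).sum() == r1.sum()

    def test_rejection_monotone_in_sorted_order(self):
        p = np.array([0.3, 0.0, 0.02, 0.9, 0.01])
        rej = inference.bayesian_fdr(p, 0.05)
        # if a value is rejected, every smaller value is too
        assert p[rej].max(initial=-1) <= p[~rej].min(initial=2)

    def test_bad_values_rejected(self):
        with pytest.raises(ValueError):
            inference.bayesian_fdr([0.1, 1.2], 0.05)
        with pytest.raises(ValueError):
            inference.bayesian_fdr([0.1], 0.0)


class TestSummarize:
    def test_normal_quantile_oracle(self):
        rng = np.random.default_rng(2)

        class _Fake:
            feature_ids = ["F1"]
            pollutant_ids = ["NO2"]

            class spec:
                variant = "naive_uni"

            def stacked(self, name):
                return rng.standard_normal((10_000, 1, 1))

        table = inference.summarize(_Fake())
        row = table.iloc[0]
        assert row["cri_lower_95"] == pytest.approx(-1.96, abs=0.08)
        assert row["cri_upper_95"] == pytest.approx(1.96, abs=0.08)
        assert row["posterior_sd"] == pytest.approx(1.0, abs=0.05)

    def test_point_mass(self):
        class _Fake:
            feature_ids = ["F1"]
            pollutant_ids = ["NO2"]

            class spec:
                variant = "naive_multiomics"

            def stacked(self, name):
                return np.full((200, 1, 1), 3.0)

        row = inference.summarize(_Fake()).iloc[0]
        assert row["posterior_mean"] == 3.0
        assert row["posterior_sd"] == 0.0
        assert row["cri_lower_95"] == row["cri_upper_95"] == 3.0
        assert row["bayes_p"] == 0.0  # all posterior mass on one side
        assert row["fdr_significant"]

    def test_multivariate_skips_fdr_uses_direct_rule(self, small_dataset):
        ds, _ = small_dataset
        spec = ModelSpec("naive_multiomics", ds.feature_ids[:2], ["NO2"])
        draws = gibbs.fit_multiomics(ds, spec, MCMCConfig(seed=4, n_chains=1,
                                                          n_iter=500, n_burnin=200))
        table = inference.summarize(draws, level=0.05)
        assert (table["fdr_significant"] == (table["bayes_p"] <= 0.05)).all()
        assert (table["cri_lower_95"] <= table["cri_upper_95"]).all()
        assert table["bayes_p"].between(0, 1).all()


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        chain = np.random.default_rng(5).standard_normal(1000)
        assert inference.gelman_rubin(np.stack([chain, chain])) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(6)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert inference.gelman_rubin(chains) > 5.0

    def test_well_mixed_chains_below_threshold(self):
        rng = np.random.default_rng(7)
        chains = rng.standard_normal((4, 2000))  # i.i.d. = ideally mixed
        assert inference.gelman_rubin(chains) < 1.1

    def test_agrees_with_arviz_rank_rhat(self):
        import arviz as az

        rng = np.random.default_rng(8)
        good = rng.standard_normal((4, 1000))
        bad = np.stack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        assert abs(inference.gelman_rubin(good) - float(az.rhat(good))) < 0.05
        assert inference.gelman_rubin(bad) > 1.5 and float(az.rhat(bad)) > 1.5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            inference.gelman_rubin(np.zeros((1, 100)))


@pytest.fixture(scope="module")
def noisy_dataset():
    beta = np.zeros((60, 1))
    beta[:10, 0] = 1.0
    cfg = SimulationConfig(n_per_group=10, n_features=60, pollutants=("NO2",),
                           Sigma_Z=np.eye(1), error_cov=1.0, beta_expo=beta, seed=44)
    return simulate_dataset(cfg)


class TestScreening:
    def test_threshold_one_retains_all(self, noisy_dataset):
        ds, _ = noisy_dataset
        assert len(inference.screen_features(ds, "NO2", 1.0)) == 60

    def test_signals_retained(self, noisy_dataset):
        ds, _ = noisy_dataset
        kept = set(inference.screen_features(ds, "NO2", 0.5))
        assert all(f in kept for f in ds.feature_ids[:10])

    def test_pvalues_match_statsmodels(self, noisy_dataset):
        """The hand-vectorized screen equals a per-feature statsmodels OLS."""
        import statsmodels.api as sm

        ds, _ = noisy_dataset
        ours = inference.screen_pvalues(ds, "NO2")
        X, e_col = inference._screen_design(ds, "NO2")
        for f in ds.feature_ids[:3]:
            fit = sm.OLS(ds.omics.loc[f].to_numpy(), X).fit()
            assert ours[f] == pytest.approx(fit.pvalues[e_col], rel=1e-6)

    def test_bad_threshold_rejected(self, noisy_dataset):
        ds, _ = noisy_dataset
        with pytest.raises(ValueError):
            inference.screen_features(ds, "NO2", 0.0)
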