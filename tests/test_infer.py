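"""Sampler correctness: exact full conditionals, contracts, reproducibility."""

import dataclasses

import numpy as np
import pytest
from scipy.special import expit

from longdcm.infer import (
    McmcConfig,
    PriorSpec,
    classify,
    fit,
    posterior_mastery_probability,
)
from longdcm.simulate import generate


class TestClassify:
    @pytest.mark.parametrize("prob, expected", [(0.51, 1), (0.50, 0), (0.49, 0)])
    def test_strict_cutpoint(self, prob, expected):
        assert classify(np.array([prob]))[0] == expected

    def test_configurable_cutpoint(self):
        assert classify(np.array([0.31]), cutpoint=0.3)[0] == 1

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify(np.array([1.2]))


def test_posterior_mastery_probability_is_plain_average():
    draws = np.zeros((2, 4, 3, 2, 1), dtype=np.uint8)  # chains, kept, N, T, K
    draws[0, ::2] = 1  # alternating across iterations in chain 0
    from longdcm.infer import PosteriorSamples

    s = PosteriorSamples(
        item_labels=[], item_draws=np.zeros((2, 4, 0)),
        gamma_labels=[], gamma_draws=np.zeros((2, 4, 2)),
        g_labels=["u0_A1", "u1_A1"], g_draws=np.zeros((2, 4, 2, 2)),
        alpha_draws=draws,
    )
    prob = posterior_mastery_probability(s)
    np.testing.assert_allclose(prob, draws.reshape(-1, 3, 2, 1).mean(axis=0))
    np.testing.assert_allclose(prob, 0.25)


class TestAlphaFullConditional:
    """With item and growth parameters fixed at truth, the mastery draws are
    i.i.d. from the exact Bernoulli full conditional, which is computable in
    closed form for a single attribute."""

    @staticmethod
    def _oracle(data):
        design = data.design
        item = design.item_parameters[0]
        p1 = expit(item.intercept + item.main_effects[0])
        p0 = expit(item.intercept)
        x = data.responses  # (N, T, I)
        loglr = (
            x * (np.log(p1) - np.log(p0)) + (1 - x) * (np.log(1 - p1) - np.log(1 - p0))
        ).sum(axis=2)
        u0 = data.true_u[:, 0][:, None]
        u1 = data.true_u[:, 1][:, None]
        eta = (design.fixed_effects.gamma00[0] + u0) + (
            design.fixed_effects.gamma10[0] + u1
        ) * data.times
        return expit(eta + loglr)

    @pytest.fixture()
    def fixed_truth_fit(self, single_attribute_design):
        data = generate(single_attribute_design)
        config = McmcConfig(
            n_chains=2, n_iterations=1100, n_burnin=100, seed=4, init="truth",
            sample_items=False, sample_growth=False,
        )
        return data, fit(data, config=config)

    def test_matches_closed_form(self, fixed_truth_fit):
        data, samples = fixed_truth_fit
        oracle = self._oracle(data)
        est = posterior_mastery_probability(samples)[:, :, 0]
        # 2000 i.i.d. draws per cell: 4 binomial sigmas
        tol = 4 * np.sqrt(oracle * (1 - oracle) / 2000) + 1e-6
        assert (np.abs(est - oracle) < tol).all()

    def test_all_correct_responses_pin_mastery(self, single_attribute_design):
        data = generate(single_attribute_design)
        x = np.array(data.responses)
        x[0, 0, :] = 1  # person 0 answers all 15 items correctly at occasion 1
        data = dataclasses.replace(data, responses=x)
        config = McmcConfig(
            n_chains=2, n_iterations=600, n_burnin=100, seed=8, init="truth",
            sample_items=False, sample_growth=False,
        )
        samples = fit(data, config=config)
        prob = posterior_mastery_probability(samples)
        assert prob[0, 0, 0] > 0.99


class TestFitContracts:
    def test_degenerate_run_returns_single_sample(self, tiny_data):
        config = McmcConfig(n_chains=2, n_iterations=11, n_burnin=10, seed=0)
        samples = fit(tiny_data, config=config)
        n, t, k = tiny_data.true_alpha.shape
        assert samples.alpha_draws.shape == (2, 1, n, t, k)
        assert samples.gamma_draws.shape == (2, 1, 2 * k)
        assert samples.g_draws.shape == (2, 1, 2 * k, 2 * k)
        assert np.isin(samples.alpha_draws, (0, 1)).all()

    def test_same_seed_reproduces_draws(self, tiny_data):
        config = McmcConfig(n_chains=2, n_iterations=60, n_burnin=30, seed=12)
        a = fit(tiny_data, config=config)
        b = fit(tiny_data, config=config)
        np.testing.assert_array_equal(a.item_draws, b.item_draws)
        np.testing.assert_array_equal(a.g_draws, b.g_draws)
        np.testing.assert_array_equal(a.alpha_draws, b.alpha_draws)

    def test_draws_respect_monotonicity_region(self, tiny_data):
        config = McmcConfig(n_chains=1, n_iterations=80, n_burnin=40, seed=3)
        samples = fit(tiny_data, config=config)
        kinds = [lbl.split("[")[0] for lbl in samples.item_labels]
        mains = samples.item_draws[:, :, [j for j, k in enumerate(kinds) if k == "lambda1"]]
        assert (mains >= 0).all()

    def test_single_occasion_rejected(self, tiny_data):
        clipped = dataclasses.replace(
            tiny_data, responses=tiny_data.responses[:, :1], times=tiny_data.times[:, :1],
            true_alpha=tiny_data.true_alpha[:, :1],
            true_mastery_prob=tiny_data.true_mastery_prob[:, :1],
        )
        with pytest.raises(ValueError):
            fit(clipped, qmatrix=tiny_data.design.qmatrix)


class TestConfigAndPriors:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iterations=100, n_burnin=100)
        with pytest.raises(ValueError):
            McmcConfig(n_chains=0)
        with pytest.raises(ValueError):
            McmcConfig(init="warmish")

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(main_sd=0.0)
        with pytest.raises(ValueError):
            PriorSpec(g_df=3.0).resolve_g(6)

    def test_truth_centered_g_prior_mean(self, g_equal):
        priors = PriorSpec().with_g_center(g_equal, weight=2.0)
        df, scale = priors.resolve_g(6)
        np.testing.assert_allclose(scale / (df - 6 - 1), g_equal.covariance)
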