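"""Synthetic-data generator: distributional fidelity and reproducibility."""

import dataclasses

import numpy as np
import pytest

from longdcm import datasets
from longdcm.growth import GMatrix, marginal_mastery_probability, mean_trajectory
from longdcm.simulate import (
    LongitudinalResponseSet,
    SimulationDesign,
    draw_random_effects,
    draw_time_scores,
    generate,
    simulate_mastery,
    simulate_responses,
)


class TestTimeScores:
    def test_zero_sd_gives_balanced_design(self):
        design = SimulationDesign.from_factors(n_persons=7, occasion_time_sd=0.0)
        times = draw_time_scores(design, np.random.default_rng(0))
        np.testing.assert_array_equal(times, np.tile([0, 8, 16, 24, 32], (7, 1)))

    def test_occasion_means_and_sd(self):
        design = SimulationDesign.from_factors(n_persons=5000, seed=0)
        times = draw_time_scores(design, np.random.default_rng(0))
        np.testing.assert_allclose(times.mean(axis=0), [0, 8, 16, 24, 32], atol=0.05)
        np.testing.assert_allclose(times.std(axis=0), 1.0, atol=0.05)

    def test_same_seed_reproduces(self):
        design = SimulationDesign.from_factors(n_persons=20)
        a = draw_time_scores(design, np.random.default_rng(3))
        b = draw_time_scores(design, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_non_monotone_times_warn(self):
        design = SimulationDesign.from_factors(
            n_persons=50, occasion_time_means=(0.0, 0.1, 0.2, 0.3, 0.4), occasion_time_sd=1.0
        )
        with pytest.warns(UserWarning, match="non-monotone"):
            draw_time_scores(design, np.random.default_rng(0))


class TestRandomEffects:
    def test_zero_matrix_gives_zero_effects(self):
        g = GMatrix(np.zeros((6, 6)))
        u = draw_random_effects(g, 10, np.random.default_rng(0))
        np.testing.assert_array_equal(u, 0.0)

    def test_empirical_covariance_matches_g(self, g_equal):
        u = draw_random_effects(g_equal, 20000, np.random.default_rng(2))
        np.testing.assert_allclose(np.cov(u.T), g_equal.covariance, atol=0.01)

    def test_intercept_correlation_reference(self, g_equal):
        u = draw_random_effects(g_equal, 20000, np.random.default_rng(2))
        r = np.corrcoef(u[:, 0], u[:, 2])[0, 1]  # u0_A1 vs u0_A2
        assert r == pytest.approx(0.90, abs=0.02)


class TestMastery:
    def test_forced_mastery(self, fixed_even, g_equal):
        fx = dataclasses.replace(fixed_even, gamma00=np.full(3, 50.0))
        u = np.zeros((100, 6))
        times = np.tile([0.0, 8.0], (100, 1))
        alpha, prob = simulate_mastery(fx, u, times, np.random.default_rng(0))
        assert alpha.all()
        np.testing.assert_allclose(prob, 1.0)

    def test_proportions_match_quadrature_oracle(self, fixed_even, g_equal):
        design = SimulationDesign.from_factors(n_persons=20000, seed=3)
        rng = np.random.default_rng(11)
        times = draw_time_scores(design, rng)
        u = draw_random_effects(g_equal, 20000, rng)
        alpha, _ = simulate_mastery(fixed_even, u, times, rng)
        for k in range(3):
            for t in range(5):
                oracle = marginal_mastery_probability(
                    fixed_even, g_equal, k, times[:, t]
                ).mean()
                assert alpha[:, t, k].mean() == pytest.approx(oracle, abs=0.01)

    def test_zero_slope_attribute_follows_marginal_not_conditional(self, fixed_uneven, g_equal):
        """With a zero average slope the conditional-at-mean trajectory is
        flat, but the population proportion still drifts toward 0.5 because
        the slope *variance* widens the logit distribution over time; the
        generator must follow the logistic-normal marginal."""
        design = SimulationDesign.from_factors(
            n_persons=20000, growth_pattern="uneven", seed=5
        )
        data = generate(design)
        assert np.ptp(mean_trajectory(fixed_uneven, design.times_mean)[0]) < 1e-12
        for t in range(5):
            oracle = marginal_mastery_probability(
                fixed_uneven, g_equal, 0, data.times[:, t]
            ).mean()
            assert data.true_alpha[:, t, 0].mean() == pytest.approx(oracle, abs=0.01)
        # and the drift is real: occasion 5 sits well above the flat 0.20
        assert data.true_alpha[:, 4, 0].mean() > 0.35


class TestResponses:
    def test_marginal_response_rates(self, qmatrix, reference_items):
        rng = np.random.default_rng(0)
        shape = (4000, 5, 3)
        for fill, expected in [(0, {1: 0.18, 2: 0.18}), (1, {1: 0.50, 2: 0.88})]:
            alpha = np.full(shape, fill, dtype=np.int8)
            x = simulate_responses(alpha, qmatrix, reference_items, rng)
            n_measured = qmatrix.entries.sum(axis=1)
            for i in range(qmatrix.n_items):
                assert x[:, :, i].mean() == pytest.approx(expected[n_measured[i]], abs=0.01)


class TestGenerate:
    def test_same_seed_is_bit_identical(self):
        design = SimulationDesign.from_factors(n_persons=40, seed=9)
        a, b = generate(design), generate(design)
        np.testing.assert_array_equal(a.responses, b.responses)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.true_u, b.true_u)

    def test_shape_contract(self):
        data = generate(SimulationDesign.from_factors(n_persons=100, seed=0))
        assert data.responses.shape == (100, 5, 30)
        assert data.times.shape == (100, 5)
        assert data.true_alpha.shape == (100, 5, 3)

    def test_degenerate_design_recovers_conditional_trajectory(self, fixed_even, qmatrix):
        """With no time jitter and no random effects the empirical mastery
        proportions converge to the conditional-at-mean trajectory (no
        logistic-normal attenuation)."""
        design = SimulationDesign.from_factors(
            n_persons=20000, seed=13, occasion_time_sd=0.0
        )
        design = dataclasses.replace(design, g=GMatrix(np.zeros((6, 6))))
        data = generate(design)
        expected = mean_trajectory(fixed_even, design.times_mean)
        for k in range(3):
            np.testing.assert_allclose(
                data.true_alpha[:, :, k].mean(axis=0), expected[k], atol=0.012
            )

    def test_design_validation(self):
        with pytest.raises(ValueError):
            SimulationDesign.from_factors(n_persons=0)
        with pytest.raises(ValueError):
            SimulationDesign.from_factors(n_occasions=1)
        with pytest.raises(ValueError):
            SimulationDesign.from_factors(growth_pattern="wiggly")
        with pytest.raises(ValueError):
            SimulationDesign.from_factors(g_design="diagonal")


def test_long_frame_roundtrip(tiny_data, tmp_path):
    tiny_data.write_csv(tmp_path / "out")
    back = LongitudinalResponseSet.read_csv(tmp_path / "out")
    np.testing.assert_array_equal(back.responses, tiny_data.responses)
    np.testing.assert_allclose(back.times, tiny_data.times)
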