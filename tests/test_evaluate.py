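"""Evaluation criteria: R-hat, error metrics, kappa, factorial effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from longdcm.evaluate import (
    anova_partial_eta2,
    bias,
    classification_report,
    cohens_kappa,
    effect_size_label,
    gelman_rubin,
    mse,
    replication_converged,
)


class TestGelmanRubin:
    def test_hand_computed_example(self):
        # chains (1,2,3,4) and (2,3,4,5): W = 5/3, B = 2
        chains = np.array([[1, 2, 3, 4], [2, 3, 4, 5.0]])
        assert gelman_rubin(chains) == pytest.approx(1.05, abs=5e-3)

    def test_identical_chains_hit_lower_limit(self):
        chains = np.array([[1, 2, 3, 4], [1, 2, 3, 4.0]])
        assert gelman_rubin(chains) == pytest.approx(0.75)

    def test_degenerate_constant_chains_flagged(self):
        same = np.full((2, 4), 3.0)
        assert gelman_rubin(same) == pytest.approx(0.75)  # B = 0 as well
        split = np.array([[1.0] * 4, [2.0] * 4])
        assert np.isinf(gelman_rubin(split))

    def test_sqrt_convention(self):
        chains = np.array([[1, 2, 3, 4], [2, 3, 4, 5.0]])
        assert gelman_rubin(chains, sqrt=True) == pytest.approx(np.sqrt(1.05), abs=5e-3)

    def test_shape_requirements(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 10)))
        with pytest.raises(ValueError):
            gelman_rubin(np.ones(10))

    def test_iid_chains_are_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((3, 1000))
        assert 0.9 < gelman_rubin(chains) < 1.1


class TestReplicationConverged:
    def test_threshold_rule(self):
        assert replication_converged([1.01, 1.05])
        assert replication_converged([1.19])
        assert not replication_converged([1.01, 1.25])
        assert not replication_converged([1.21])

    def test_dict_input_and_nonfinite(self):
        assert not replication_converged({"a": 1.0, "b": np.inf})

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            replication_converged([])


class TestBiasMse:
    def test_reference_values(self):
        est = [0.1, 0.2, 0.3]
        assert bias(est, 0.2) == pytest.approx(0.0)
        assert mse(est, 0.2) == pytest.approx(0.00667, abs=5e-5)

    def test_exact_and_offset(self):
        assert bias([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert bias([1.5, 2.5], [1.0, 2.0]) == pytest.approx(0.5)
        assert mse([1.5, 2.5], [1.0, 2.0]) == pytest.approx(0.25)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bias([1.0, 2.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 10_000))
    def test_decomposition_identity(self, seed):
        """MSE = bias^2 + variance of the errors (population denominators)."""
        rng = np.random.default_rng(seed)
        est = rng.standard_normal(25)
        tru = rng.standard_normal(25)
        err = est - tru
        assert mse(est, tru) == pytest.approx(
            bias(est, tru) ** 2 + err.var(ddof=0), abs=1e-12
        )


class TestKappa:
    @staticmethod
    def _from_confusion(tp, fn, fp, tn):
        truth = np.concatenate([np.ones(tp + fn), np.zeros(fp + tn)])
        pred = np.concatenate([np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn)])
        return truth, pred

    def test_hand_computed_confusion_table(self):
        truth, pred = self._from_confusion(40, 10, 5, 45)
        assert cohens_kappa(truth, pred) == pytest.approx(0.70)

    def test_perfect_agreement(self):
        truth = np.array([0, 1, 0, 1])
        assert cohens_kappa(truth, truth) == 1.0

    def test_single_level_prediction_is_missing(self):
        truth = np.array([0, 1, 0, 1])
        pred = np.zeros(4)
        assert np.isnan(cohens_kappa(truth, pred))

    def test_label_swap_invariance(self):
        truth, pred = self._from_confusion(30, 12, 7, 51)
        assert cohens_kappa(1 - truth, 1 - pred) == pytest.approx(cohens_kappa(truth, pred))

    @given(st.integers(0, 10_000))
    def test_against_sklearn(self, seed):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 2, 60)
        pred = rng.integers(0, 2, 60)
        if np.unique(truth).size < 2 or np.unique(pred).size < 2:
            return
        assert cohens_kappa(truth, pred) == pytest.approx(
            sklearn_metrics.cohen_kappa_score(truth, pred), abs=1e-12
        )


class TestClassificationReport:
    def test_rates_and_missing_kappa(self):
        true_alpha = np.array([[[1], [1]], [[0], [1]], [[0], [0]]])  # (3, 2, 1)
        est_prob = np.array([[[0.1], [0.9]], [[0.2], [0.8]], [[0.1], [0.2]]])
        report = classification_report(true_alpha, est_prob)
        first = report[report.occasion == 1].iloc[0]
        # all predictions non-mastery at occasion 1: kappa undefined
        assert np.isnan(first.kappa)
        assert first.rate_true_masters == 0.0
        assert first.rate_true_nonmasters == 1.0
        second = report[report.occasion == 2].iloc[0]
        assert second.kappa == 1.0

    def test_probability_bias_against_generating_probability(self):
        true_alpha = np.ones((4, 1, 1), dtype=int)
        est_prob = np.full((4, 1, 1), 0.8)
        true_prob = np.full((4, 1, 1), 0.7)
        report = classification_report(true_alpha, est_prob, true_prob=true_prob)
        assert report.prob_bias.iloc[0] == pytest.approx(0.1)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            classification_report(np.ones((2, 2, 1)), np.ones((2, 2, 2)))


class TestAnova:
    def test_single_factor_hand_example(self):
        frame = pd.DataFrame(
            {"y": [1, 2, 3, 3, 4, 5], "grp": ["a", "a", "a", "b", "b", "b"]}
        )
        table = anova_partial_eta2(frame, "y", ["grp"])
        assert table.partial_eta2.iloc[0] == pytest.approx(0.60)
        assert table.label.iloc[0] == "large"

    def test_constant_outcome_gives_zero(self):
        frame = pd.DataFrame({"y": [2.0] * 8, "grp": ["a", "b"] * 4})
        table = anova_partial_eta2(frame, "y", ["grp"])
        assert table.partial_eta2.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_factor_interaction_rows(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {
                "y": rng.standard_normal(24),
                "f1": np.repeat(["a", "b"], 12),
                "f2": np.tile(np.repeat(["x", "y", "z"], 4), 2),
            }
        )
        table = anova_partial_eta2(frame, "y", ["f1", "f2"])
        assert set(table.effect) == {"f1", "f2", "f1:f2"}

    def test_single_level_factor_rejected(self):
        frame = pd.DataFrame({"y": [1.0, 2.0], "grp": ["a", "a"]})
        with pytest.raises(ValueError):
            anova_partial_eta2(frame, "y", ["grp"])


def test_effect_size_labels_follow_convention():
    assert effect_size_label(0.005) == "negligible"
    assert effect_size_label(0.05) == "small"
    assert effect_size_label(0.06) == "medium"
    assert effect_size_label(0.14) == "large"
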