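"""Policy evaluation: error models, Wilson intervals, the Monte Carlo
sampler against the exact enumeration oracle, and analytic limits."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.proportion import proportion_confint

from ncfet import (ErrorModel, NTMAConfig, OvulationPMF,
                   error_model_from_confusion, evaluate_exact,
                   evaluate_monte_carlo, simulate_outcome, wilson_ci)
from ncfet.model import ConfusionReport
from ncfet.records import CLASS_ORDER

CFG = NTMAConfig()
PMF = OvulationPMF.from_truncated_normal()


def random_error_model(rng: np.random.Generator, concentration=2.0) -> ErrorModel:
    """Dirichlet rows biased toward the diagonal."""
    alpha = np.full((9, 9), 0.3) + np.eye(9) * concentration
    rows = np.stack([rng.dirichlet(a) for a in alpha])
    return ErrorModel(rows)


class TestErrorModel:
    def test_rows_must_be_stochastic(self):
        bad = np.eye(9)
        bad[0, 0] = 0.5
        with pytest.raises(ValueError, match="sum to 1"):
            ErrorModel(bad)

    def test_identity_and_uniform(self):
        assert np.array_equal(ErrorModel.identity().matrix, np.eye(9))
        assert np.allclose(ErrorModel.uniform().matrix, 1 / 9)

    def test_mixing_toward_uniform(self):
        mixed = ErrorModel.identity().mix_with_uniform(0.5)
        assert mixed.matrix[0, 0] == pytest.approx(0.5 + 0.5 / 9)

    def test_from_confusion_identity(self):
        counts = np.diag(np.arange(1, 10))
        report = ConfusionReport(counts=counts,
                                 class_names=tuple(c.name for c in CLASS_ORDER))
        assert np.allclose(error_model_from_confusion(report).matrix, np.eye(9))

    def test_from_confusion_normalizes_columns(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 30, size=(9, 9))
        report = ConfusionReport(counts=counts,
                                 class_names=tuple(c.name for c in CLASS_ORDER))
        em = error_model_from_confusion(report)
        assert np.allclose(em.matrix.sum(axis=1), 1.0)
        # P(pred | actual) comes from the actual-class column
        assert em.matrix[0, 3] == pytest.approx(counts[3, 0] / counts[:, 0].sum())

    def test_from_confusion_empty_column_falls_back_to_identity(self):
        counts = np.diag([5] * 9)
        counts[3, 3] = 0
        report = ConfusionReport(counts=counts,
                                 class_names=tuple(c.name for c in CLASS_ORDER))
        with pytest.warns(UserWarning, match="absent"):
            em = error_model_from_confusion(report)
        assert em.matrix[3, 3] == 1.0


class TestWilsonCI:
    def test_against_independent_implementation(self):
        lo, hi = wilson_ci(5, 10, 0.95)
        ref_lo, ref_hi = proportion_confint(5, 10, alpha=0.05, method="wilson")
        assert lo == pytest.approx(ref_lo, abs=1e-9)
        assert hi == pytest.approx(ref_hi, abs=1e-9)
        assert (lo, hi) == pytest.approx((0.2366, 0.7634), abs=1e-3)

    def test_zero_successes_bounds(self):
        lo, hi = wilson_ci(0, 10)
        assert lo >= 0.0 and hi > 0.0

    @given(st.integers(min_value=1, max_value=500), st.data())
    @settings(deadline=None, max_examples=100)
    def test_interval_contains_point_estimate(self, n, data):
        successes = data.draw(st.integers(min_value=0, max_value=n))
        lo, hi = wilson_ci(successes, n)
        # the containment is algebraically exact; allow float rounding at p=0,1
        assert lo - 1e-12 <= successes / n <= hi + 1e-12

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)


class TestSimulateOutcome:
    def test_identity_model_day16(self, rng):
        outcome, n_tests = simulate_outcome(16, ErrorModel.identity(), CFG, rng)
        assert (outcome, n_tests) == ("correct", 3)

    def test_identity_model_early_ovulation(self, rng):
        outcome, n_tests = simulate_outcome(6, ErrorModel.identity(), CFG, rng)
        assert (outcome, n_tests) == ("no_prediction", 1)

    def test_always_zero_model_transfers_wrong_immediately(self, rng):
        matrix = np.zeros((9, 9))
        matrix[:, 6] = 1.0  # always predict the same-day class
        outcome, n_tests = simulate_outcome(20, ErrorModel(matrix), CFG, rng)
        assert (outcome, n_tests) == ("incorrect", 1)


class TestEvaluateExact:
    def test_identity_model_analytic_limits(self):
        report = evaluate_exact(PMF, ErrorModel.identity(), CFG)
        assert report.incorrect_rate == 0.0
        assert report.no_prediction_rate == pytest.approx(
            PMF.mass_at_most(CFG.initial_test_day - 2), abs=1e-12)
        assert report.correct_rate + report.no_prediction_rate \
            + report.aborted_rate == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_pmf_mean_tests(self):
        pmf = OvulationPMF(np.array([16]), np.array([1.0]))
        report = evaluate_exact(pmf, ErrorModel.identity(), CFG)
        assert report.mean_tests == pytest.approx(3.0, abs=1e-12)
        assert report.correct_rate == pytest.approx(1.0)

    def test_node_budget_enforced(self):
        with pytest.raises(ValueError, match="node"):
            evaluate_exact(PMF, ErrorModel.identity(), CFG, node_budget=10)

    def test_correct_rate_degrades_monotonically_with_noise(self):
        rates = []
        for lam in (0.0, 0.25, 0.5, 1.0):
            em = ErrorModel.identity().mix_with_uniform(lam)
            rates.append(evaluate_exact(PMF, em, CFG).correct_rate)
        assert all(b <= a + 1e-12 for a, b in zip(rates, rates[1:]))

    def test_aborted_mass_negligible_under_mild_degradation(self):
        em = ErrorModel.identity().mix_with_uniform(0.25)
        report = evaluate_exact(PMF, em, CFG)
        assert report.aborted_rate < 0.001


class TestEvaluateMonteCarlo:
    def test_rates_partition_to_one(self, rng):
        em = random_error_model(rng)
        report = evaluate_monte_carlo(PMF, em, CFG, n_samples=2000,
                                      n_repeats=5, rng=rng)
        total = (report.correct_rate + report.incorrect_rate
                 + report.no_prediction_rate + report.aborted_rate)
        assert total == pytest.approx(1.0, abs=1e-12)
        for r in range(5):
            per = sum(report.per_repeat[k][r] for k in
                      ("correct", "incorrect", "no_prediction", "aborted"))
            assert per == pytest.approx(1.0, abs=1e-12)

    def test_identity_model_matches_analytic_within_wilson(self, rng):
        report = evaluate_monte_carlo(PMF, ErrorModel.identity(), CFG,
                                      n_samples=10_000, n_repeats=5, rng=rng)
        assert report.incorrect_rate == 0.0
        lo, hi = report.ci["no_prediction_rate"]
        assert lo <= PMF.mass_at_most(CFG.initial_test_day - 2) <= hi

    def test_agreement_with_exact_oracle(self):
        rng = np.random.default_rng(42)
        em = random_error_model(rng)
        exact = evaluate_exact(PMF, em, CFG)
        mc = evaluate_monte_carlo(PMF, em, CFG, n_samples=20_000, n_repeats=2,
                                  rng=rng)
        n = 40_000
        for attr in ("correct_rate", "incorrect_rate", "no_prediction_rate"):
            p = getattr(exact, attr)
            se = max(np.sqrt(p * (1 - p) / n), 1e-6)
            assert abs(getattr(mc, attr) - p) < 4 * se, attr

    def test_wilson_width_shrinks_with_sample_size(self):
        em = ErrorModel.identity().mix_with_uniform(0.3)
        widths = []
        for n in (5000, 10_000):
            report = evaluate_monte_carlo(PMF, em, CFG, n_samples=n,
                                          n_repeats=4,
                                          rng=np.random.default_rng(7))
            lo, hi = report.ci["correct_rate"]
            widths.append(hi - lo)
        ratio = widths[1] / widths[0]
        assert abs(ratio - 1 / np.sqrt(2)) < 0.2 / np.sqrt(2)

    def test_scalar_and_batch_samplers_agree_in_distribution(self):
        # same trajectory law: compare correct-rate from the scalar walker
        # with the exact probability, for a fixed ovulation day
        rng = np.random.default_rng(11)
        em = ErrorModel.identity().mix_with_uniform(0.4)
        pmf = OvulationPMF(np.array([16]), np.array([1.0]))
        exact = evaluate_exact(pmf, em, CFG)
        outcomes = [simulate_outcome(16, em, CFG, rng)[0] for _ in range(4000)]
        rate = np.mean([o == "correct" for o in outcomes])
        se = np.sqrt(exact.correct_rate * (1 - exact.correct_rate) / 4000)
        assert abs(rate - exact.correct_rate) < 4 * se

    def test_summary_is_table_shaped(self):
        report = evaluate_exact(PMF, ErrorModel.identity(), CFG)
        text = report.summary()
        assert "Correct prediction rate (%)" in text
        assert "Average number of tests" in text


class TestOvulationPMF:
    def test_truncated_normal_mass_and_mode(self):
        assert PMF.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert PMF.days[np.argmax(PMF.probs)] == 16

    def test_empirical_pmf(self):
        pmf = OvulationPMF.from_observed_days([14, 14, 16, 18])
        assert pmf.probs[pmf.days == 14] == pytest.approx(0.5)
        assert pmf.mean() == pytest.approx(15.5)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            OvulationPMF(np.array([10, 11]), np.array([0.6, 0.6]))
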