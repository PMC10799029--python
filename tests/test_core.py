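"""Scoring, 0-1 loss and the penalised selection objective."""

import math

import numpy as np
import pytest

import maxlogit as ml
from maxlogit.core import INACTIVE, total_misclassifications

from conftest import toy_cohort

# the explicitly stated four-gene factors of the first study cohort
CF1 = ml.CompetingFactor(-90.3645, (2.8598, 5.5149, -0.8795), ("APP", "PSMC2", "SLC20A1"))
CF2 = ml.CompetingFactor(-26.5288, (0.5692, 3.1516, -1.0474), ("CXCL8", "PSMC2", "SLC20A1"))


class TestLinearFactorScore:
    def test_published_equation_on_printed_expression(self):
        # (APP, PSMC2, SLC20A1) printed at two decimals; score printed at -4.05384
        score = ml.linear_factor_score((14.46, 10.12, 12.36), CF1)
        assert score == pytest.approx(-4.05384, abs=0.05)

    def test_zero_coefficients_return_intercept(self):
        f = ml.CompetingFactor(3.25, (0.0, 0.0), ("a", "b"))
        assert ml.linear_factor_score((123.0, -7.0), f) == 3.25

    def test_matches_elementwise_multiply_accumulate(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            coefs = rng.normal(size=3)
            row = rng.normal(size=3)
            b0 = rng.normal()
            f = ml.CompetingFactor(b0, tuple(coefs), ("a", "b", "c"))
            expected = b0
            for x, c in zip(row, coefs):  # independent accumulate
                expected += x * c
            assert ml.linear_factor_score(row, f) == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="does not match"):
            ml.linear_factor_score((1.0, 2.0), CF1)

    def test_non_finite_input_raises(self):
        with pytest.raises(ValueError, match="non-finite"):
            ml.linear_factor_score((np.nan, 1.0, 2.0), CF1)

    def test_inactive_factor_loses_every_comparison(self):
        f = ml.CompetingFactor.inactive(("a",))
        assert ml.linear_factor_score((5.0,), f) == INACTIVE
        assert ml.linear_factor_score((5.0,), f) < -1e300


class TestMaxLogodds:
    def _classifier(self, intercepts, cohort="c"):
        factors = [ml.CompetingFactor(b, (0.0,), ("g1",)) for b in intercepts]
        partition = ml.GenePartition((("g1",),) * len(intercepts))
        return ml.MaxLogisticClassifier(partition, {cohort: factors})

    def test_published_three_factor_row(self):
        # printed factor scores of a control sample; the first one wins
        clf = self._classifier((-1.15919, -5.59369, -9.92037))
        value, winners = ml.max_logodds([0.0], clf, "c", ["g1"])
        assert value == -1.15919
        assert winners == (0,)

    def test_single_active_factor_reduces_to_its_score(self):
        clf = self._classifier((2.5,))
        value, _ = ml.max_logodds([0.0], clf, "c", ["g1"])
        assert value == 2.5

    def test_matches_loop_maximum(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=5)
        clf = self._classifier(tuple(scores))
        value, _ = ml.max_logodds([0.0], clf, "c", ["g1"])
        best = scores[0]
        for s in scores[1:]:
            if s > best:
                best = s
        assert value == best

    def test_all_inactive_raises(self):
        factors = [ml.CompetingFactor.inactive(("g1",))]
        clf = ml.MaxLogisticClassifier(ml.GenePartition((("g1",),)), {"c": factors})
        with pytest.raises(ValueError, match="inactive"):
            ml.max_logodds([0.0], clf, "c", ["g1"])

    def test_factor_order_does_not_change_predictions(self, small_cohorts):
        cohort = small_cohorts[0]
        g = cohort.gene_ids
        f1 = ml.CompetingFactor(-1.0, (0.5, 0.2), (g[0], g[1]))
        f2 = ml.CompetingFactor(0.5, (-0.3,), (g[2],))
        a = ml.MaxLogisticClassifier(
            ml.GenePartition((f1.genes, f2.genes)), {cohort.cohort_id: [f1, f2]}
        )
        b = ml.MaxLogisticClassifier(
            ml.GenePartition((f2.genes, f1.genes)), {cohort.cohort_id: [f2, f1]}
        )
        assert np.array_equal(a.predict(cohort), b.predict(cohort))
        assert ml.misclassification_count(a, cohort) == ml.misclassification_count(b, cohort)


class TestRiskProbability:
    @pytest.mark.parametrize(
        "logodds, printed, decimals",
        [(-4.05384, 0.01706, 5), (8.352782, 0.999764, 6), (0.0, 0.5, 12)],
    )
    def test_published_and_symmetric_values(self, logodds, printed, decimals):
        assert ml.risk_probability(logodds) == pytest.approx(printed, abs=10.0**-decimals)

    def test_numerically_stable_for_extreme_logodds(self):
        assert ml.risk_probability(1000.0) == 1.0
        assert ml.risk_probability(-1000.0) == pytest.approx(0.0, abs=1e-300)
        assert ml.risk_probability(INACTIVE) == 0.0

    def test_nan_raises(self):
        with pytest.raises(ValueError):
            ml.risk_probability(float("nan"))


class TestClassify:
    def test_tumor_above_threshold(self):
        assert ml.classify(0.696302) == 1

    def test_tie_at_threshold_is_control(self):
        # forced by the error-count objective, which charges p <= 0.5 tumors
        assert ml.classify(0.5) == 0

    def test_control_below_threshold(self):
        assert ml.classify(0.01706) == 0

    def test_bad_threshold_raises(self):
        with pytest.raises(ValueError):
            ml.classify(0.4, threshold=1.0)


def _published_dataset1_cohort():
    # printed worked-example rows of the first cohort (labels 0,0,1,1)
    expr = [
        [14.46, 2.57, 10.12, 12.36],
        [14.71, 2.84, 9.95, 12.12],
        [13.32, 5.64, 10.92, 9.79],
        [14.11, 5.66, 11.10, 10.39],
    ]
    return toy_cohort(expr, [0, 0, 1, 1], gene_ids=["APP", "CXCL8", "PSMC2", "SLC20A1"])


class TestMisclassificationCount:
    def test_published_rows_are_error_free(self):
        cohort = _published_dataset1_cohort()
        clf = ml.MaxLogisticClassifier(
            ml.GenePartition((CF1.genes, CF2.genes)), {"toy": [CF1, CF2]}
        )
        assert ml.misclassification_count(clf, cohort) == 0

    def test_all_half_probabilities_charge_every_tumor(self):
        cohort = _published_dataset1_cohort()
        zero = ml.CompetingFactor(0.0, (0.0,), ("APP",))
        clf = ml.MaxLogisticClassifier(ml.GenePartition((("APP",),)), {"toy": [zero]})
        assert ml.misclassification_count(clf, cohort) == int(cohort.labels.sum())

    def test_matches_per_sample_enumeration(self):
        rng = np.random.default_rng(5)
        cohort = toy_cohort(rng.normal(size=(8, 2)), rng.integers(0, 2, 8).tolist())
        f = ml.CompetingFactor(0.3, (1.1, -0.7), ("g1", "g2"))
        clf = ml.MaxLogisticClassifier(ml.GenePartition((f.genes,)), {"toy": [f]})
        expected = 0
        for i in range(8):
            p = ml.risk_probability(ml.linear_factor_score(cohort.expression[i], f))
            pred = 1 if p > 0.5 else 0
            expected += int(pred != cohort.labels[i])
        assert ml.misclassification_count(clf, cohort) == expected

    def test_missing_genes_named_in_error(self):
        cohort = _published_dataset1_cohort()
        f = ml.CompetingFactor(0.0, (1.0,), ("NOSUCH",))
        clf = ml.MaxLogisticClassifier(ml.GenePartition((f.genes,)), {"toy": [f]})
        with pytest.raises(KeyError, match="NOSUCH"):
            ml.misclassification_count(clf, cohort)


class TestSparsityPenalty:
    def test_single_group_closed_form(self):
        for s in range(1, 12):
            assert ml.sparsity_penalty(s, 1) == pytest.approx(s - 1.0)

    def test_hand_arithmetic(self):
        assert ml.sparsity_penalty(4, 2) == pytest.approx(4 - 5 / 9)
        assert ml.sparsity_penalty(4, 2) == pytest.approx(31 / 9)

    def test_fraction_monotone_decreasing_in_both_arguments(self):
        # constant (= 1) in s at G = 1, strictly decreasing once G >= 2
        frac = lambda s, G: s - ml.sparsity_penalty(s, G)
        for s in range(1, 10):
            for G in range(1, 5):
                assert frac(s + 1, G) <= frac(s, G)
                assert frac(s, G + 1) < frac(s, G)
                if G >= 2:
                    assert frac(s + 1, G) < frac(s, G)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ml.sparsity_penalty(0, 1)


class TestPenalizedObjective:
    def _instance(self):
        cohort = _published_dataset1_cohort()
        clf = ml.MaxLogisticClassifier(
            ml.GenePartition((CF1.genes, CF2.genes)), {"toy": [CF1, CF2]}
        )
        return clf, [cohort]

    def test_zero_error_case_equals_one_plus_penalty(self):
        clf, cohorts = self._instance()
        # union {APP, CXCL8, PSMC2, SLC20A1} of size 4, two groups, no errors
        literal = ml.penalized_objective(clf, cohorts, ml.PenaltyConfig(0.0, 1.0), form="literal")
        assert literal == pytest.approx(1.0 + 31 / 9)

    def test_log_form_is_log_of_literal(self):
        clf, cohorts = self._instance()
        pen = ml.PenaltyConfig(0.5, 2.0)
        literal = ml.penalized_objective(clf, cohorts, pen, form="literal")
        logform = ml.penalized_objective(clf, cohorts, pen, form="log")
        assert logform == pytest.approx(math.log(literal), rel=1e-12)

    def test_log_form_preserves_ordering_of_literal(self):
        rng = np.random.default_rng(9)
        cohort = toy_cohort(rng.normal(size=(12, 3)), rng.integers(0, 2, 12).tolist())
        pen = ml.PenaltyConfig(0.0, 1.0)
        values = []
        for _ in range(15):
            G = rng.integers(1, 3)
            groups = []
            for _ in range(G):
                size = int(rng.integers(1, 4))
                genes = tuple(rng.choice(["g1", "g2", "g3"], size=size, replace=False))
                groups.append(genes)
            factors = [
                ml.CompetingFactor(rng.normal(), tuple(rng.normal(size=len(g))), g)
                for g in groups
            ]
            clf = ml.MaxLogisticClassifier(ml.GenePartition(tuple(groups)), {"toy": factors})
            values.append(
                (
                    ml.penalized_objective(clf, [cohort], pen, form="literal"),
                    ml.penalized_objective(clf, [cohort], pen, form="log"),
                )
            )
        order_literal = sorted(range(len(values)), key=lambda i: values[i][0])
        order_log = sorted(range(len(values)), key=lambda i: values[i][1])
        assert order_literal == order_log

    def test_each_extra_error_strictly_increases_first_term(self):
        cohort = _published_dataset1_cohort()
        good = ml.MaxLogisticClassifier(
            ml.GenePartition((CF1.genes, CF2.genes)), {"toy": [CF1, CF2]}
        )
        # flipping one tumor label adds exactly one error at fixed coefficients
        flipped = toy_cohort(
            cohort.expression, [0, 0, 1, 0], gene_ids=list(cohort.gene_ids)
        )
        pen = ml.PenaltyConfig(0.0, 1.0)
        assert total_misclassifications(good, [flipped]) == 1
        assert ml.penalized_objective(good, [flipped], pen, form="literal") > ml.penalized_objective(
            good, [cohort], pen, form="literal"
        )

    def test_duplicate_group_changes_penalty_not_predictions(self):
        clf, cohorts = self._instance()
        dup = ml.MaxLogisticClassifier(
            ml.GenePartition((CF1.genes, CF2.genes, CF2.genes)),
            {"toy": [CF1, CF2, CF2]},
        )
        assert np.array_equal(dup.predict(cohorts[0]), clf.predict(cohorts[0]))
        pen = ml.PenaltyConfig(0.0, 1.0)
        assert ml.penalized_objective(dup, cohorts, pen, form="literal") > ml.penalized_objective(
            clf, cohorts, pen, form="literal"
        )


class TestSingleFactorReduction:
    def test_one_factor_decisions_match_plain_logistic_rule(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(40, 3))
        beta = np.array([0.8, -1.2, 0.4])
        b0 = 0.3
        f = ml.CompetingFactor(b0, tuple(beta), ("g1", "g2", "g3"))
        cohort = toy_cohort(X, rng.integers(0, 2, 40).tolist())
        clf = ml.MaxLogisticClassifier(ml.GenePartition((f.genes,)), {"toy": [f]})
        linear = b0 + X @ beta
        plain = (1.0 / (1.0 + np.exp(-linear)) > 0.5).astype(int)
        assert np.array_equal(clf.predict(cohort), plain)
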