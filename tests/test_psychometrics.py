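"""Reliability, known-groups, ROC and correlation-comparison statistics."""

from __future__ import annotations

import numpy as np
import pytest

from queds import (
    ValidationError,
    average_interitem_correlation,
    compare_dependent_correlations,
    compare_independent_correlations,
    cronbach_alpha,
    known_groups_ttest,
    roc_analysis,
    sensitivity_specificity,
    validation_report,
)
from queds import test_retest as retest_correlation  # avoid pytest collection

from conftest import brute_auc

# 4 subjects x 3 items used for the hand-worked reliability values
WORKED_TABLE = np.array([[1, 1, 1], [1, 1, 0], [0, 0, 1], [0, 0, 0]])


class TestCronbachAlpha:
    def test_hand_worked_value(self):
        # item variances 1/3 each (sum 1); totals 3,2,1,0 -> variance 5/3
        # alpha = 3/2 * (1 - 1/(5/3)) = 3/5
        assert cronbach_alpha(WORKED_TABLE) == pytest.approx(0.6)

    def test_duplicated_columns_give_one(self):
        col = np.array([1, 0, 1, 0, 1])[:, None]
        assert cronbach_alpha(np.hstack([col, col])) == pytest.approx(1.0)

    def test_zero_covariance_gives_zero(self):
        x = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])  # orthogonal columns
        assert cronbach_alpha(x) == pytest.approx(0.0)

    def test_item_order_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, size=(30, 6))
        perm = rng.permutation(6)
        assert cronbach_alpha(x[:, perm]) == pytest.approx(cronbach_alpha(x))

    def test_zero_total_variance_is_nan(self):
        x = np.array([[1, 0], [0, 1], [1, 0]])
        with pytest.warns(UserWarning):
            assert np.isnan(cronbach_alpha(x))


class TestInterItemCorrelation:
    def test_hand_worked_value(self):
        # r12 = 1, r13 = r23 = 0 -> mean 1/3
        assert average_interitem_correlation(WORKED_TABLE) == pytest.approx(1 / 3)

    def test_constant_columns_excluded_with_warning(self):
        x = np.array([[1, 1, 1], [0, 1, 0], [1, 1, 1], [0, 1, 0]])
        with pytest.warns(UserWarning, match="constant"):
            assert average_interitem_correlation(x) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(42)
        x = rng.integers(0, 2, size=(20000, 2))
        assert abs(average_interitem_correlation(x)) < 3 / np.sqrt(20000)


class TestRetest:
    def test_identity_and_sign_flip(self):
        v = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert retest_correlation(v, v) == pytest.approx(1.0)
        assert retest_correlation(v, -v) == pytest.approx(-1.0)

    def test_hand_worked_pairs(self):
        assert retest_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_degenerate_variance(self):
        with pytest.warns(UserWarning):
            assert np.isnan(retest_correlation([1, 1, 1], [1, 2, 3]))


class TestKnownGroupsTTest:
    def test_hand_worked_pooled_t(self):
        res = known_groups_ttest([4, 5, 6], [1, 2, 3])
        assert res["t"] == pytest.approx(-3 / np.sqrt(2 / 3))
        assert res["df"] == 4

    def test_identical_groups(self):
        res = known_groups_ttest([1, 2, 3], [1, 2, 3])
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_swap_flips_sign(self):
        a, b = [4, 5, 9], [1, 2, 3]
        assert known_groups_ttest(a, b)["t"] == pytest.approx(
            -known_groups_ttest(b, a)["t"]
        )

    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        clin = rng.normal(28, 6, 38)
        nc = rng.normal(6, 6, 265)
        res = known_groups_ttest(clin, nc)
        ref = stats.ttest_ind(nc, clin, equal_var=True)
        assert res["t"] == pytest.approx(ref.statistic)
        assert res["p"] == pytest.approx(ref.pvalue)
        assert res["df"] == 301

    def test_degenerate_variance(self):
        with pytest.raises(ValidationError):
            known_groups_ttest([2, 2], [2, 2])


class TestRoc:
    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == pytest.approx(1.0)
        assert r.youden_j == pytest.approx(1.0)

    def test_label_permuted_duplicates(self):
        r = roc_analysis([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert r.auc == pytest.approx(0.5)

    def test_hand_worked_ties(self):
        # 6 wins + 2 half-ties over 9 pairs
        r = roc_analysis([1, 2, 3, 2, 3, 4], [0, 0, 0, 1, 1, 1])
        assert r.auc == pytest.approx(7 / 9)

    def test_pair_count_oracle_on_random_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(4, 51))
            scores = rng.integers(0, 12, n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_analysis(scores, labels).auc == pytest.approx(
                brute_auc(scores, labels)
            )

    def test_against_sklearn(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(23)
        scores = rng.integers(0, 42, 100)
        labels = rng.integers(0, 2, 100)
        assert roc_analysis(scores, labels).auc == pytest.approx(
            sklearn.roc_auc_score(labels, scores)
        )

    def test_youden_threshold_tie_to_smallest(self):
        # J = 0 at every candidate threshold; the smallest one is reported
        r = roc_analysis([1, 2, 1, 2], [0, 1, 1, 0])
        assert r.optimal_threshold == 1
        # and with a separation gap the unique maximizer is reported
        assert roc_analysis([1, 1, 3, 3], [0, 0, 1, 1]).optimal_threshold == 3

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_sensitivity_specificity_convention(self):
        sens, spec = sensitivity_specificity([1, 5, 10, 20], [0, 0, 1, 1], 10)
        assert sens == 1.0 and spec == 1.0  # score >= threshold is positive


class TestCorrelationComparisons:
    def test_equal_dependent_correlations_give_zero(self):
        res = compare_dependent_correlations(0.5, 0.5, 0.3, 100)
        assert res["z"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_convergent_divergent_worked_example(self):
        # total-score correlations with two related scales on one sample
        res = compare_dependent_correlations(0.72, 0.39, 0.37, 113)
        assert res["z"] == pytest.approx(4.156312398255859)
        assert res["p"] < 0.001

    def test_equal_independent_correlations_give_zero(self):
        res = compare_independent_correlations(0.4, 50, 0.4, 50)
        assert res["z"] == pytest.approx(0.0)

    def test_independent_hand_value(self):
        z = (np.arctanh(0.6) - np.arctanh(0.2)) / np.sqrt(1 / 47 + 1 / 97)
        assert compare_independent_correlations(0.6, 50, 0.2, 100)["z"] == pytest.approx(z)

    @pytest.mark.parametrize("bad", [1.0, -1.0])
    def test_unit_correlation_rejected(self, bad):
        with pytest.raises(ValidationError):
            compare_dependent_correlations(bad, 0.2, 0.1, 50)
        with pytest.raises(ValidationError):
            compare_independent_correlations(bad, 50, 0.2, 50)


class TestValidationReport:
    def test_battery_on_synthetic_cohort(self):
        import pandas as pd

        from queds import calibrate, cohort_to_frame, default_config, generate

        cfg = calibrate(default_config())
        nc = cohort_to_frame(generate(cfg, 120, "nonclinical", seed=10))
        cl = cohort_to_frame(generate(cfg, 30, "clinical", seed=11))
        df = pd.concat([nc, cl], ignore_index=True)
        rep = validation_report(df)
        assert rep["n_subjects"] == 150
        assert {"alpha_total", "alpha_cognitive", "alpha_somatic", "alpha_affective"} <= set(
            rep["reliability"]
        )
        kg = rep["known_groups"]
        assert kg["t"] < 0 and kg["df"] == 148
        assert 0.5 < kg["auc"] <= 1.0
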