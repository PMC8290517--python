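"""ROC/PR metrics, bootstrap CIs, correlation and group tests."""

import numpy as np
import pytest
from scipy import stats

from gliomics import (
    binary_metrics,
    bootstrap_ci,
    confusion_at_threshold,
    group_posterior_ttest,
    performance_report,
    point_biserial,
    pr_analysis,
    roc_analysis,
)
from gliomics.errors import InvalidInputError, UndefinedMetricError

from _oracles import auc_pairwise_bruteforce


class TestConfusion:
    def test_perfect_classifier(self):
        y = np.array([1, 1, 0, 0, 1])
        cm = confusion_at_threshold(y.astype(float), y)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (3, 2, 0, 0)
        assert binary_metrics(cm)["accuracy"] == 1.0

    def test_counts_partition(self, rng):
        p = rng.uniform(size=50)
        y = (rng.uniform(size=50) < 0.4).astype(int)
        if y.sum() in (0, 50):
            y[0] = 1 - y[0]
        cm = confusion_at_threshold(p, y)
        assert cm.n == 50
        assert cm.tp + cm.fn == y.sum() and cm.tn + cm.fp == 50 - y.sum()

    def test_metric_identities(self, rng):
        p = rng.uniform(size=80)
        y = np.repeat([0, 1], 40)
        m = binary_metrics(confusion_at_threshold(p, y))
        if m["precision"] + m["sensitivity"] > 0:
            f1 = 2 * m["precision"] * m["sensitivity"] / (m["precision"] + m["sensitivity"])
            assert m["f1"] == pytest.approx(f1)

    def test_no_positive_predictions_warns(self):
        p = np.full(10, 0.1)
        y = np.array([1, 0] * 5)
        with pytest.warns(UserWarning, match="precision"):
            m = binary_metrics(confusion_at_threshold(p, y))
        assert m["precision"] == 0.0 and m["f1"] == 0.0


class TestRoc:
    def test_hand_example(self):
        auc, _, _ = roc_analysis([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = np.round(rng.uniform(size=30), 2)  # rounding forces some ties
        y = np.repeat([0, 1], 15)
        auc, _, _ = roc_analysis(p, y)
        assert auc == pytest.approx(auc_pairwise_bruteforce(p, y), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        p = rng.uniform(size=40)
        y = np.repeat([0, 1], 20)
        a1, _, _ = roc_analysis(p, y)
        a2, _, _ = roc_analysis(1.0 / (1.0 + np.exp(-5 * p)), y)
        assert a1 == pytest.approx(a2)

    def test_one_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_analysis([0.2, 0.4], [1, 1])


class TestPr:
    def test_f1_at_threshold(self):
        p = np.array([0.9, 0.8, 0.3, 0.6, 0.2, 0.1])
        y = np.array([1, 1, 1, 0, 0, 0])
        f1, _, _ = pr_analysis(p, y)
        # TP=2 FN=1 FP=1 TN=2 -> precision=recall=2/3 -> F1=2/3
        assert f1 == pytest.approx(2 / 3)

    def test_equal_precision_recall(self):
        # harmonic mean of equals is the value itself (exercised above)
        prec = rec = 0.7755
        assert 2 * prec * rec / (prec + rec) == pytest.approx(prec)


class TestBootstrap:
    def test_deterministic_given_seed(self, rng):
        p = rng.uniform(size=60)
        y = np.repeat([0, 1], 30)
        fn = lambda pp, yy: roc_analysis(pp, yy)[0]
        a = bootstrap_ci(fn, p, y, n_boot=200, seed=7)
        b = bootstrap_ci(fn, p, y, n_boot=200, seed=7)
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)

    def test_constant_metric_zero_width(self):
        y = np.repeat([0, 1], 20)
        p = y.astype(float)
        fn = lambda pp, yy: binary_metrics(confusion_at_threshold(pp, yy))["accuracy"]
        ci = bootstrap_ci(fn, p, y, n_boot=100, seed=0)
        assert ci.ci_lower == ci.ci_upper == ci.estimate == 1.0

    def test_estimate_within_ci(self, rng):
        p = np.clip(rng.normal(0.5, 0.2, size=100) + 0.2 * np.repeat([0, 1], 50), 0, 1)
        y = np.repeat([0, 1], 50)
        fn = lambda pp, yy: roc_analysis(pp, yy)[0]
        ci = bootstrap_ci(fn, p, y, n_boot=500, seed=1)
        assert ci.ci_lower - 0.02 <= ci.estimate <= ci.ci_upper + 0.02

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(3)
        widths = {}
        for n in (50, 500):
            y = np.repeat([0, 1], n // 2)
            p = np.clip(0.4 + 0.2 * y + rng.normal(0, 0.2, size=n), 0, 1)
            fn = lambda pp, yy: roc_analysis(pp, yy)[0]
            ci = bootstrap_ci(fn, p, y, n_boot=400, seed=n)
            widths[n] = ci.ci_upper - ci.ci_lower
        ratio = widths[50] / widths[500]
        assert 1.5 < ratio < 6.0  # ~sqrt(10) with sampling slack


class TestPointBiserial:
    def test_equals_pearson_on_01_labels(self):
        p = np.array([0.2, 0.9, 0.4, 0.8, 0.3, 0.7])
        y = np.array([0, 1, 0, 1, 0, 1])
        r, pv = point_biserial(p, y)
        rp, pp_ = stats.pearsonr(p, y.astype(float))
        assert r == pytest.approx(rp, abs=1e-12)
        assert pv == pytest.approx(pp_, abs=1e-12)

    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1])
        r, _ = point_biserial(y.astype(float), y)
        assert r == pytest.approx(1.0)

    def test_null_r_small(self, rng):
        rs = []
        for _ in range(10):
            p = rng.uniform(size=200)
            y = np.repeat([0, 1], 100)
            rs.append(point_biserial(p, y)[0])
        assert abs(np.mean(rs)) < 0.05


class TestGroupTtest:
    def test_identical_means(self):
        p = np.array([0.3, 0.5, 0.7, 0.3, 0.5, 0.7])
        y = np.array([1, 1, 1, 0, 0, 0])
        t, pv, _ = group_posterior_ttest(p, y)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert pv == pytest.approx(1.0)

    def test_hand_computation_welch(self):
        # groups {1,2,3} vs {4,5,6}: t = -3/sqrt(2/3), df = 4, p = 0.021312
        p = np.array([1, 2, 3, 4, 5, 6]) / 10.0
        y = np.array([1, 1, 1, 0, 0, 0])
        t, pv, summ = group_posterior_ttest(p, y)
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-10)
        assert pv == pytest.approx(0.02131164, rel=1e-5)
        assert summ["codeletion"]["n"] == 3

    def test_degenerate_group_rejected(self):
        # one group with a single member cannot be tested
        with pytest.raises(InvalidInputError):
            group_posterior_ttest([0.1, 0.9, 0.5], [1, 0, 1])


def test_performance_report_structure(rng):
    p = np.clip(0.3 + 0.4 * np.repeat([0, 1], 30) + rng.normal(0, 0.2, 60), 0.01, 0.99)
    y = np.repeat([0, 1], 30)
    rep = performance_report(p, y, n_boot=100, seed=0)
    for key in ("auc", "accuracy", "sensitivity", "specificity", "precision", "f1"):
        assert rep[key]["ci_lower"] <= rep[key]["value"] <= rep[key]["ci_upper"]
    assert 0 < rep["point_biserial"]["r"] <= 1
    assert rep["posterior_ttest"]["p"] < 0.05
    import json

    json.dumps(rep)  # fully serializable
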