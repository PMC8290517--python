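"""Performance battery on pooled out-of-fold posterior probabilities.

ROC analysis (AUC by the trapezoidal rule, equivalent to the tie-corrected
Mann-Whitney statistic), precision-recall analysis with the F1 score at the
0.5 operating threshold, class-stratified percentile bootstrap confidence
intervals (1000 resamples), point-biserial correlation between posteriors
and the 0/1 labels, and a two-sample t-test comparing posteriors between the
codeletion and non-codeletion groups (Welch by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from .errors import InvalidInputError, UndefinedMetricError, UnstableCiError

__all__ = [
    "ConfusionCounts",
    "MetricWithCi",
    "confusion_at_threshold",
    "binary_metrics",
    "roc_analysis",
    "pr_analysis",
    "bootstrap_ci",
    "point_biserial",
    "group_posterior_ttest",
    "performance_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricWithCi:
    estimate: float
    ci_lower: float
    ci_upper: float
    n_boot: int = 1000


def _check(posteriors, labels):
    p = np.asarray(posteriors, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if p.shape != y.shape:
        raise InvalidInputError("posteriors and labels differ in length")
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("posteriors must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("both classes must be present")
    return p, y


def confusion_at_threshold(posteriors, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Integer confusion counts with positive = posterior >= threshold."""
    p, y = _check(posteriors, labels)
    pred = p >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def binary_metrics(cm: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision and F1 from one matrix."""
    if cm.tp + cm.fp == 0:
        warnings.warn("no positive predictions: precision undefined, reported as 0")
        precision = 0.0
    else:
        precision = cm.tp / (cm.tp + cm.fp)
    sensitivity = cm.tp / (cm.tp + cm.fn)
    f1 = 0.0 if precision + sensitivity == 0 else 2 * precision * sensitivity / (precision + sensitivity)
    return {
        "accuracy": (cm.tp + cm.tn) / cm.n,
        "sensitivity": sensitivity,
        "specificity": cm.tn / (cm.tn + cm.fp),
        "precision": precision,
        "f1": f1,
    }


def roc_analysis(posteriors, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """(AUC, fpr, tpr). Trapezoidal AUC equals the midrank Mann-Whitney statistic."""
    p, y = _check(posteriors, labels)
    fpr, tpr, _ = roc_curve(y, p)
    return float(_trapezoid_auc(fpr, tpr)), fpr, tpr


def pr_analysis(posteriors, labels, threshold: float = 0.5):
    """F1 at the operating threshold plus the full precision-recall curve."""
    p, y = _check(posteriors, labels)
    m = binary_metrics(confusion_at_threshold(p, y, threshold))
    precision, recall, _ = precision_recall_curve(y, p)
    return m["f1"], precision, recall


def bootstrap_ci(
    metric_fn,
    posteriors,
    labels,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> MetricWithCi:
    """Class-stratified percentile bootstrap CI of ``metric_fn(posteriors, labels)``.

    Subjects are resampled with replacement within each class, so every
    resample contains both classes. Resamples on which the metric is
    undefined are redrawn (an error is raised if more than 10% fail).
    """
    p, y = _check(posteriors, labels)
    if len(y) < 10:
        raise InvalidInputError("bootstrap needs at least 10 subjects")
    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    estimate = float(metric_fn(p, y))
    vals = np.empty(n_boot)
    failures = 0
    for b in range(n_boot):
        for _attempt in range(3):
            idx = np.concatenate(
                [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
            )
            try:
                vals[b] = metric_fn(p[idx], y[idx])
                break
            except (UndefinedMetricError, ZeroDivisionError):
                failures += 1
        else:
            vals[b] = np.nan
    if failures > 0.1 * n_boot or np.isnan(vals).any():
        raise UnstableCiError(f"metric undefined on {failures} bootstrap resamples")
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return MetricWithCi(estimate=estimate, ci_lower=float(lo), ci_upper=float(hi), n_boot=n_boot)


def point_biserial(posteriors, labels) -> tuple[float, float]:
    """Point-biserial r (Pearson with a 0/1 variable) and its t-based p-value."""
    p, y = _check(posteriors, labels)
    if np.std(p) == 0:
        raise UndefinedMetricError("posterior variance is zero")
    res = stats.pointbiserialr(y, p)
    return float(res.correlation), float(res.pvalue)


def group_posterior_ttest(posteriors, labels, equal_var: bool = False):
    """Two-sample t-test on posteriors between label groups (Welch by default).

    Returns (t, p, summaries) where summaries holds boxplot-ready per-group
    statistics (median, quartiles, mean, n).
    """
    p, y = _check(posteriors, labels)
    g1, g0 = p[y == 1], p[y == 0]
    if len(g1) < 2 or len(g0) < 2:
        raise InvalidInputError("need at least 2 subjects per group")
    res = stats.ttest_ind(g1, g0, equal_var=equal_var)
    summaries = {
        label: {
            "n": len(g),
            "mean": float(np.mean(g)),
            "median": float(np.median(g)),
            "q1": float(np.quantile(g, 0.25)),
            "q3": float(np.quantile(g, 0.75)),
        }
        for label, g in (("codeletion", g1), ("non-codeletion", g0))
    }
    return float(res.statistic), float(res.pvalue), summaries


def _metric_closure(name: str):
    def fn(p, y):
        if name == "auc":
            return roc_analysis(p, y)[0]
        return binary_metrics(confusion_at_threshold(p, y))[name]

    return fn


def performance_report(
    posteriors, labels, n_boot: int = 1000, seed: int = 0
) -> dict:
    """The full battery: all metrics with bootstrap CIs plus the statistics.

    The JSON-serializable return maps metric name ->
    {value, ci_lower, ci_upper}, plus ROC/PR curves, point-biserial r/p and
    the posterior-group t-test.
    """
    p, y = _check(posteriors, labels)
    report: dict = {}
    for name in ("auc", "accuracy", "sensitivity", "specificity", "precision", "f1"):
        m = bootstrap_ci(_metric_closure(name), p, y, n_boot=n_boot, seed=seed)
        report[name] = {"value": m.estimate, "ci_lower": m.ci_lower, "ci_upper": m.ci_upper}
    _, fpr, tpr = roc_analysis(p, y)
    _, prec, rec = pr_analysis(p, y)
    report["roc_curve"] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
    report["pr_curve"] = {"precision": prec.tolist(), "recall": rec.tolist()}
    r, rp = point_biserial(p, y)
    report["point_biserial"] = {"r": r, "p": rp}
    t, tp, summ = group_posterior_ttest(p, y)
    report["posterior_ttest"] = {"t": t, "p": tp, "groups": summ}
    return report
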