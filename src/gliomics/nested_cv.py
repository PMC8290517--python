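"""10 x 10 nested cross-validation with embedded selection and tuning.

The outer loop splits subjects into 10 stratified folds; within each outer
training set the elastic net selects features and the RBF-SVM tunes its
hyperparameters, each with its own inner 10-fold CV; the fold's model then
scores only the held-out subjects. Every subject therefore receives exactly
one out-of-fold posterior from a model that never saw it, and the run
produces 10 distinct optimal models. Features selected in all 10 outer
loops form the consensus ("most valuable") feature set.

All z-scoring, selection, tuning and calibration use training rows only;
fold seeds are derived deterministically from the plan seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .classifier import SvmConfig, TrainedClassifier, predict_posterior, svm_tune_fit
from .errors import InvalidInputError, InvalidSubgroupError, StratificationError
from .selection import EnetConfig, SelectedFeatureSet, enet_select

__all__ = [
    "FoldPlan",
    "FoldResult",
    "NestedCvResult",
    "make_fold_plan",
    "run_nested_cv",
    "consensus_features",
    "subgroup_run",
    "misclassified_in_group",
]


@dataclass(frozen=True)
class FoldPlan:
    """Outer-fold assignment (0..n_folds-1) per subject."""

    assignments: pd.Series
    n_folds: int
    stratified: bool
    seed: int

    def fold_indices(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(train positions, test positions) for outer fold k."""
        test = np.flatnonzero(self.assignments.to_numpy() == k)
        train = np.flatnonzero(self.assignments.to_numpy() != k)
        return train, test


def make_fold_plan(labels, n_folds: int = 10, seed: int = 0, stratified: bool = True) -> FoldPlan:
    """Deterministic (stratified) outer fold assignment.

    Stratification keeps per-fold class counts within one subject of perfect
    balance; with a 41% prevalence unstratified folds risk near-empty
    classes, so stratified is the default.
    """
    labels = pd.Series(labels)
    y = labels.to_numpy()
    if len(y) < n_folds:
        raise InvalidInputError(f"{len(y)} subjects cannot fill {n_folds} folds")
    if stratified and np.bincount(y).min() < n_folds:
        raise StratificationError("a class has fewer members than the number of folds")
    splitter = (
        StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    )
    assign = np.empty(len(y), dtype=np.int64)
    for k, (_tr, te) in enumerate(splitter.split(np.zeros((len(y), 1)), y)):
        assign[te] = k
    return FoldPlan(
        assignments=pd.Series(assign, index=labels.index, name="outer_fold"),
        n_folds=n_folds,
        stratified=stratified,
        seed=seed,
    )


@dataclass
class FoldResult:
    fold: int
    selection: SelectedFeatureSet
    model: TrainedClassifier
    test_subjects: tuple[str, ...]
    posteriors: np.ndarray


@dataclass
class NestedCvResult:
    folds: list[FoldResult]
    pooled_posterior: pd.Series  # one out-of-fold posterior per subject
    plan: FoldPlan
    features: pd.DataFrame = field(repr=False, default=None)
    labels: pd.Series = field(repr=False, default=None)

    @property
    def selected_counts_per_fold(self) -> list[int]:
        return [len(f.selection.feature_names) for f in self.folds]


def _fold_seed(seed: int, fold: int) -> int:
    return int((seed * 1009 + 7 * fold + 1) % (2**31 - 1))


def run_nested_cv(
    features: pd.DataFrame,
    labels,
    enet_cfg: EnetConfig | None = None,
    svm_cfg: SvmConfig | None = None,
    plan: FoldPlan | None = None,
    seed: int = 0,
) -> NestedCvResult:
    """Run the full nested CV and pool out-of-fold posteriors.

    Per outer fold: z-score predictor columns on the 9 training folds,
    elastic-net select, tune and fit the SVM on the selected columns, then
    score the held-out fold. All predictor columns (radiomic, age, sex) are
    treated uniformly.
    """
    labels = pd.Series(labels).loc[features.index]
    if features.isna().any().any():
        raise InvalidInputError("feature table has missing values")
    # normalize memory layout so results are bit-reproducible regardless of
    # how the caller's frame was assembled (reduction order follows strides)
    features = pd.DataFrame(
        np.ascontiguousarray(features.to_numpy(dtype=np.float64)),
        index=features.index,
        columns=features.columns,
    )
    plan = plan or make_fold_plan(labels, seed=seed)
    enet_cfg = enet_cfg or EnetConfig()
    svm_cfg = svm_cfg or SvmConfig()

    y = labels.to_numpy()
    pooled = pd.Series(np.full(len(labels), np.nan), index=features.index, name="posterior")
    folds: list[FoldResult] = []
    for k in range(plan.n_folds):
        tr, te = plan.fold_indices(k)
        Xtr, ytr = features.iloc[tr], y[tr]
        mean = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=0).replace(0.0, 1.0)
        fs = _fold_seed(plan.seed, k)
        selection = enet_select((Xtr - mean) / sd, ytr, enet_cfg, seed=fs)
        model = svm_tune_fit(
            Xtr[list(selection.feature_names)], ytr, svm_cfg, seed=fs
        )
        post = predict_posterior(model, features.iloc[te])
        pooled.iloc[te] = post
        folds.append(
            FoldResult(
                fold=k,
                selection=selection,
                model=model,
                test_subjects=tuple(features.index[te]),
                posteriors=post,
            )
        )
    assert not pooled.isna().any()
    return NestedCvResult(folds=folds, pooled_posterior=pooled, plan=plan,
                          features=features, labels=labels)


def consensus_features(result: NestedCvResult, min_folds: int | None = None) -> pd.DataFrame:
    """Selection counts across outer folds and the all-folds consensus set.

    Returns a frame with one row per ever-selected feature: ``selected_times``,
    ``consensus`` (selected in all folds, or >= ``min_folds`` if given), and a
    Welch two-sample t-test p-value comparing the feature between classes —
    the publication-style "valuable features" report. P-values are raw
    (no multiplicity correction), matching per-feature reporting practice.
    """
    n_folds = result.plan.n_folds
    need = n_folds if min_folds is None else min_folds
    counts: dict[str, int] = {}
    for f in result.folds:
        for name in f.selection.feature_names:
            counts[name] = counts.get(name, 0) + 1
    rows = []
    y = result.labels.to_numpy()
    for name, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        pval = np.nan
        if result.features is not None:
            x = result.features[name].to_numpy(dtype=float)
            pval = float(stats.ttest_ind(x[y == 1], x[y == 0], equal_var=False).pvalue)
        rows.append({"feature": name, "selected_times": c, "consensus": c >= need, "p_value": pval})
    return pd.DataFrame(rows).set_index("feature")


def subgroup_run(
    features: pd.DataFrame,
    labels,
    flags,
    keep_value,
    enet_cfg: EnetConfig | None = None,
    svm_cfg: SvmConfig | None = None,
    seed: int = 0,
    n_folds: int = 10,
) -> NestedCvResult:
    """Re-run the identical pipeline on the subgroup where ``flags == keep_value``.

    Typical use: restrict to IDH-mutant subjects, excluding the wildtype
    astrocytomas whose imaging phenotype may differ.
    """
    flags = pd.Series(flags).loc[features.index]
    labels = pd.Series(labels).loc[features.index]
    sel = flags == keep_value
    sub_labels = labels[sel]
    if sub_labels.nunique() < 2:
        raise InvalidSubgroupError("subgroup does not contain both classes")
    plan = make_fold_plan(sub_labels, n_folds=n_folds, seed=seed)
    return run_nested_cv(features[sel], sub_labels, enet_cfg, svm_cfg, plan)


def misclassified_in_group(result: NestedCvResult, flags, flag_value) -> tuple[int, int]:
    """(misclassified, total) among subjects with the given flag, at threshold 0.5."""
    flags = pd.Series(flags).loc[result.pooled_posterior.index]
    sel = flags == flag_value
    pred = (result.pooled_posterior[sel] >= 0.5).astype(int)
    truth = result.labels[sel]
    return int((pred != truth).sum()), int(sel.sum())
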