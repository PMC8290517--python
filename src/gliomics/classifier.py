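"""RBF-kernel SVM with inner-CV hyperparameter tuning and Platt calibration.

The classifier is tuned over log-spaced grids of box constraint C (the soft
margin penalty) and kernel scale s, with the RBF kernel parameterized as
K(x, x') = exp(-||x - x'||² / s²) (so sklearn's gamma = 1/s²). The grid pair
minimizing inner 10-fold misclassification loss is chosen, ties broken
toward smaller C then larger s (stronger regularization). Decision values
are mapped to posterior probabilities of codeletion by a Platt sigmoid
fitted on inner-CV (out-of-fold) decision values only.

Default grid endpoints: C in [10^(1/3), 10^3], s in [10, 10^(7/3)].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import DegenerateLabelsError, InvalidInputError, SchemaMismatchError

__all__ = ["SvmConfig", "TrainedClassifier", "svm_tune_fit", "predict_posterior"]


@dataclass(frozen=True)
class SvmConfig:
    box_grid: tuple[float, ...] = tuple(np.logspace(1.0 / 3.0, 3.0, 9))
    scale_grid: tuple[float, ...] = tuple(np.logspace(1.0, 7.0 / 3.0, 5))
    n_inner_folds: int = 10

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.box_grid) or any(s <= 0 for s in self.scale_grid):
            raise InvalidInputError("hyperparameter grids must be strictly positive")


@dataclass
class TrainedClassifier:
    """A fitted fold model: scaler + selected features + SVM + Platt map."""

    feature_names: tuple[str, ...]
    scaler_mean: np.ndarray  # per selected feature, from training rows only
    scaler_sd: np.ndarray
    box_constraint: float | None = None
    kernel_scale: float | None = None
    platt_a: float = -1.0
    platt_b: float = 0.0
    svc: SVC | None = None
    prior_posterior: float | None = None  # prior-only fallback (empty feature set)
    inner_cv_loss: float = float("nan")

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise SchemaMismatchError(f"unknown/missing features: {missing[:5]}")
        X = np.ascontiguousarray(features[list(self.feature_names)].to_numpy(dtype=np.float64))
        return (X - self.scaler_mean) / self.scaler_sd

    def decision_values(self, features: pd.DataFrame) -> np.ndarray:
        if self.svc is None:
            return np.zeros(len(features))
        return self.svc.decision_function(self.transform(features))


def _platt_fit(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt's sigmoid fit with target smoothing: p = 1/(1+exp(A f + B))."""
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab):
        # with p = 1/(1+e^z): -sum[t log p + (1-t) log(1-p)] = sum[log(1+e^z) - (1-t) z]
        z = ab[0] * decision + ab[1]
        return float(np.sum(np.logaddexp(0.0, z) - (1.0 - t) * z))

    def grad(ab):
        z = ab[0] * decision + ab[1]
        s = 1.0 / (1.0 + np.exp(np.clip(-z, -500, 500)))  # sigma(z) = 1 - p
        d = s - (1.0 - t)
        return np.array([np.sum(d * decision), np.sum(d)])

    b0 = np.log((n_neg + 1.0) / (n_pos + 1.0))
    res = minimize(nll, x0=np.array([-1.0, b0]), jac=grad, method="BFGS")
    return float(res.x[0]), float(res.x[1])


def _platt_apply(decision: np.ndarray, a: float, b: float) -> np.ndarray:
    z = np.clip(a * decision + b, -500, 500)
    return np.clip(1.0 / (1.0 + np.exp(z)), 1e-12, 1.0 - 1e-12)


def svm_tune_fit(
    features: pd.DataFrame,
    labels,
    cfg: SvmConfig | None = None,
    seed: int = 0,
    prescaled: bool = False,
) -> TrainedClassifier:
    """Tune (C, s) by inner 10-fold misclassification loss, fit, and calibrate.

    ``features`` are the training rows restricted to the selected features.
    Columns are z-scored with training statistics unless ``prescaled``.
    An empty feature frame yields a prior-only classifier that emits the
    training prevalence as its posterior, with a warning.
    """
    cfg = cfg or SvmConfig()
    y = np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise DegenerateLabelsError("need at least 2 subjects per class")

    if features.shape[1] == 0:
        warnings.warn("empty feature set: training a prior-only classifier")
        return TrainedClassifier(
            feature_names=(),
            scaler_mean=np.empty(0),
            scaler_sd=np.empty(0),
            prior_posterior=float(y.mean()),
        )

    Xraw = np.ascontiguousarray(features.to_numpy(dtype=np.float64))
    if prescaled:
        mean, sd = np.zeros(Xraw.shape[1]), np.ones(Xraw.shape[1])
    else:
        mean = Xraw.mean(axis=0)
        sd = Xraw.std(axis=0)
        sd[sd == 0] = 1.0
    X = (Xraw - mean) / sd

    skf = StratifiedKFold(n_splits=cfg.n_inner_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    combos = [(c, s) for c in cfg.box_grid for s in cfg.scale_grid]
    errors = np.zeros(len(combos))
    for tr, va in splits:
        for k, (c, s) in enumerate(combos):
            clf = SVC(C=c, gamma=1.0 / s**2, kernel="rbf")
            clf.fit(X[tr], y[tr])
            errors[k] += int(np.sum(clf.predict(X[va]) != y[va]))
    loss = errors / len(y)
    # ties -> smaller box constraint, then larger kernel scale
    order = sorted(range(len(combos)), key=lambda k: (loss[k], combos[k][0], -combos[k][1]))
    best_c, best_s = combos[order[0]]

    # out-of-fold decision values at the chosen pair, for calibration only
    oof = np.empty(len(y))
    for tr, va in splits:
        clf = SVC(C=best_c, gamma=1.0 / best_s**2, kernel="rbf")
        clf.fit(X[tr], y[tr])
        oof[va] = clf.decision_function(X[va])
    a, b = _platt_fit(oof, y)

    svc = SVC(C=best_c, gamma=1.0 / best_s**2, kernel="rbf")
    svc.fit(X, y)
    return TrainedClassifier(
        feature_names=tuple(features.columns),
        scaler_mean=mean,
        scaler_sd=sd,
        box_constraint=float(best_c),
        kernel_scale=float(best_s),
        platt_a=a,
        platt_b=b,
        svc=svc,
        inner_cv_loss=float(loss[order[0]]),
    )


def predict_posterior(model: TrainedClassifier, features: pd.DataFrame) -> np.ndarray:
    """Posterior probability of 1p/19q codeletion for each row, in (0, 1).

    The hard label is posterior >= 0.5. Test columns are transformed with
    the model's stored training z-score parameters.
    """
    if model.prior_posterior is not None:
        return np.full(len(features), np.clip(model.prior_posterior, 1e-12, 1 - 1e-12))
    f = model.svc.decision_function(model.transform(features))
    return _platt_apply(f, model.platt_a, model.platt_b)
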