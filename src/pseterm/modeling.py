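"""Classifier zoo, normalization, metrics and repeated cross-validation.

Metrics follow the complement form common in this literature: with N+
positives, N- negatives, N+- positives mistaken as negatives (fn) and
N-+ negatives mistaken as positives (fp),

    Sn  = 1 - fn/N+            Sp  = 1 - fp/N-
    Acc = 1 - (fn + fp)/(N+ + N-)
    MCC = (1 - (fn/N+ + fp/N-)) / sqrt((1 + (fp-fn)/N+) (1 + (fn-fp)/N-))

which are algebraically identical to the standard TP/TN/FP/FN forms.
Cross-validation is stratified 5-fold, repeated with fresh partitions;
reports carry means and standard errors over repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .features import FeatureMatrix

__all__ = [
    "MinMaxNormalizer",
    "minmax_fit",
    "minmax_apply",
    "ConfusionCounts",
    "MetricsReport",
    "metrics",
    "roc_auc",
    "CVConfig",
    "ModelSpec",
    "model_spec",
    "MODEL_NAMES",
    "repeated_cv",
    "grid_search",
]


# ---------------------------------------------------------------------------
# Min-max normalization (mapminmax-style)


@dataclass
class MinMaxNormalizer:
    """Affine per-feature map of the training min/max onto a target range.

    Constant training features map to the range midpoint.  Transforming
    unseen data may produce values outside the range; they are not
    clipped, since clipping would hide genuine extrapolation.
    """

    feature_range: tuple[float, float] = (0.0, 1.0)
    min_: np.ndarray | None = None
    max_: np.ndarray | None = None

    def fit(self, X: np.ndarray | FeatureMatrix) -> "MinMaxNormalizer":
        values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        self.min_ = values.min(axis=0)
        self.max_ = values.max(axis=0)
        return self

    def transform(self, X: np.ndarray | FeatureMatrix) -> np.ndarray:
        if self.min_ is None or self.max_ is None:
            raise RuntimeError("MinMaxNormalizer must be fitted before transforming")
        values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        low, high = self.feature_range
        span = self.max_ - self.min_
        constant = span == 0
        scaled = (values - self.min_) / np.where(constant, 1.0, span)
        out = low + scaled * (high - low)
        mid = (low + high) / 2.0
        out[:, constant] = mid
        return out


def minmax_fit(
    X_train: np.ndarray | FeatureMatrix, feature_range: tuple[float, float] = (0.0, 1.0)
) -> MinMaxNormalizer:
    return MinMaxNormalizer(feature_range).fit(X_train)


def minmax_apply(scaler: MinMaxNormalizer, X: np.ndarray | FeatureMatrix) -> np.ndarray:
    return scaler.transform(X)


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ConfusionCounts:
    """Class sizes and the two error counts of a binary prediction."""

    n_pos: int
    n_neg: int
    fn: int  # positives mistaken as negative
    fp: int  # negatives mistaken as positive

    def __post_init__(self) -> None:
        if not (0 <= self.fn <= self.n_pos and 0 <= self.fp <= self.n_neg):
            raise ValueError(f"inconsistent confusion counts: {self}")

    @staticmethod
    def from_predictions(y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionCounts":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        return ConfusionCounts(
            n_pos=int((yt == 1).sum()),
            n_neg=int((yt == 0).sum()),
            fn=int(((yt == 1) & (yp == 0)).sum()),
            fp=int(((yt == 0) & (yp == 1)).sum()),
        )


@dataclass(frozen=True)
class MetricsReport:
    """Sn/Sp/Acc/MCC (and AUC when scores exist) with standard errors."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float = float("nan")
    se_sn: float = 0.0
    se_sp: float = 0.0
    se_acc: float = 0.0
    se_mcc: float = 0.0
    se_auc: float = 0.0
    n_repeats: int = 1
    skipped_folds: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "sn": self.sn, "sp": self.sp, "acc": self.acc, "mcc": self.mcc,
            "auc": self.auc, "se_sn": self.se_sn, "se_sp": self.se_sp,
            "se_acc": self.se_acc, "se_mcc": self.se_mcc, "se_auc": self.se_auc,
            "n_repeats": self.n_repeats, "skipped_folds": self.skipped_folds,
        }


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Sn, Sp, Acc, MCC from confusion counts (AUC needs scores)."""
    if c.n_pos == 0 or c.n_neg == 0:
        raise ValueError("metrics need both classes present")
    sn = 1.0 - c.fn / c.n_pos
    sp = 1.0 - c.fp / c.n_neg
    acc = 1.0 - (c.fn + c.fp) / (c.n_pos + c.n_neg)
    f1 = 1.0 + (c.fp - c.fn) / c.n_pos
    f2 = 1.0 + (c.fn - c.fp) / c.n_neg
    if f1 <= 0 or f2 <= 0:
        mcc = 0.0
    else:
        mcc = (1.0 - (c.fn / c.n_pos + c.fp / c.n_neg)) / np.sqrt(f1 * f2)
    return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=float(mcc))


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> tuple[pd.DataFrame, float]:
    """ROC curve points and trapezoid AUC (rank-average on tied scores)."""
    yt = np.asarray(y_true)
    sc = np.asarray(scores, dtype=float)
    if not np.isfinite(sc).all():
        raise ValueError("scores must be finite")
    if len(np.unique(yt)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(yt, sc)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, float(_sk_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# Model zoo


def _float_range(start: float, stop: float, step: float) -> list[float]:
    n = int(round((stop - start) / step)) + 1
    return [round(start + i * step, 10) for i in range(n)]


_ESTIMATOR_COUNTS = list(range(10, 1001, 50))  # 20 grid points

#: Hyperparameter search grids per algorithm (libsvm-style exponential
#: grid for the SVM; tenth steps for learning rates; 50-step estimator
#: counts for the ensembles).
MODEL_GRIDS: dict[str, dict[str, list]] = {
    "svc": {
        "C": [2.0**e for e in range(-5, 16, 2)],
        "gamma": [2.0**e for e in range(-15, -4, 2)],
    },
    "naive_bayes": {},
    "logistic": {
        "C": _float_range(0.1, 1.0, 0.1),
        "solver": ["newton-cg", "lbfgs", "liblinear", "sag"],
    },
    "decision_tree": {
        "min_samples_split": list(range(2, 31, 2)),
        "max_depth": list(range(1, 11)),
    },
    "mlp": {"alpha": [0.001, 0.01, 0.1, 0.5, 1.0, 1.5]},
    "knn": {},
    "bagging": {"n_estimators": _ESTIMATOR_COUNTS},
    "adaboost": {
        "n_estimators": _ESTIMATOR_COUNTS,
        "learning_rate": _float_range(0.1, 1.0, 0.1),
    },
    "gbm": {
        "learning_rate": _float_range(0.1, 1.0, 0.1),
        "n_estimators": _ESTIMATOR_COUNTS,
        "max_depth": list(range(1, 11)),
    },
    "xgb": {
        "n_estimators": _ESTIMATOR_COUNTS,
        "learning_rate": _float_range(0.1, 1.0, 0.1),
    },
}

_SCALED_ALGORITHMS = {"svc", "logistic", "knn", "mlp"}
_BASE_ALGORITHMS = {"svc", "logistic", "decision_tree", "naive_bayes"}

MODEL_NAMES = tuple(MODEL_GRIDS)


@dataclass(frozen=True)
class ModelSpec:
    """One classifier configuration: algorithm, optional base learner,
    search grid and whether min-max scaling applies.

    Scaling applies to margin/distance learners (SVM, logistic
    regression, k-NN, perceptron) and to ensembles over them, not to
    tree or probability models.
    """

    algorithm: str
    base: str | None = None
    grid: dict = field(default_factory=dict)
    needs_scaling: bool = False
    params: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{self.algorithm}({self.base})" if self.base else self.algorithm

    def with_params(self, **params) -> "ModelSpec":
        return replace(self, params={**self.params, **params})

    def build(self, seed: int = 0):
        return _build_estimator(self, seed)


def model_spec(algorithm: str, base: str | None = None, **params) -> ModelSpec:
    """Look up a zoo member, e.g. ``model_spec('xgb')`` or
    ``model_spec('adaboost', base='decision_tree')``."""
    if algorithm not in MODEL_GRIDS:
        raise ValueError(f"unknown algorithm {algorithm!r}; known: {MODEL_NAMES}")
    if algorithm in ("bagging", "adaboost"):
        base = base or "decision_tree"
        if base not in _BASE_ALGORITHMS:
            raise ValueError(f"base must be one of {sorted(_BASE_ALGORITHMS)}")
        needs_scaling = base in _SCALED_ALGORITHMS
    else:
        if base is not None:
            raise ValueError(f"{algorithm!r} takes no base learner")
        needs_scaling = algorithm in _SCALED_ALGORITHMS
    return ModelSpec(
        algorithm=algorithm,
        base=base,
        grid=dict(MODEL_GRIDS[algorithm]),
        needs_scaling=needs_scaling,
        params=params,
    )


def _base_estimator(name: str, seed: int):
    if name == "svc":
        return SVC(random_state=seed)
    if name == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    raise ValueError(name)


def _build_estimator(spec: ModelSpec, seed: int):
    p = dict(spec.params)
    alg = spec.algorithm
    if alg == "svc":
        return SVC(random_state=seed, **p)
    if alg == "naive_bayes":
        return GaussianNB(**p)
    if alg == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed, **p)
    if alg == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **p)
    if alg == "mlp":
        return MLPClassifier(max_iter=500, random_state=seed, **p)
    if alg == "knn":
        return KNeighborsClassifier(**p)
    if alg == "bagging":
        return BaggingClassifier(
            estimator=_base_estimator(spec.base, seed), random_state=seed, **p
        )
    if alg == "adaboost":
        return AdaBoostClassifier(
            estimator=_base_estimator(spec.base, seed), random_state=seed, **p
        )
    if alg == "gbm":
        return GradientBoostingClassifier(random_state=seed, **p)
    if alg == "xgb":
        p.setdefault("n_estimators", 100)
        return XGBClassifier(
            tree_method="hist",
            eval_metric="logloss",
            n_jobs=1,
            random_state=seed,
            **p,
        )
    raise ValueError(alg)


def decision_scores(estimator, X: np.ndarray) -> np.ndarray:
    """Continuous positive-class score for ROC purposes."""
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    return estimator.decision_function(X)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass(frozen=True)
class CVConfig:
    """Repeated k-fold settings; each repeat redraws the partition."""

    folds: int = 5
    repeats: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


TransformHook = Callable[[np.ndarray, np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]


def _summarize(per_repeat: list[MetricsReport], skipped: int) -> MetricsReport:
    def agg(attr: str) -> tuple[float, float]:
        vals = np.array([getattr(r, attr) for r in per_repeat])
        se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        return float(vals.mean()), float(se)

    sn, se_sn = agg("sn")
    sp, se_sp = agg("sp")
    acc, se_acc = agg("acc")
    mcc, se_mcc = agg("mcc")
    aucs = np.array([r.auc for r in per_repeat])
    if np.isnan(aucs).any():
        auc_m, se_auc = float("nan"), 0.0
    else:
        auc_m = float(aucs.mean())
        se_auc = float(aucs.std(ddof=1) / np.sqrt(len(aucs))) if len(aucs) > 1 else 0.0
    return MetricsReport(
        sn=sn, sp=sp, acc=acc, mcc=mcc, auc=auc_m,
        se_sn=se_sn, se_sp=se_sp, se_acc=se_acc, se_mcc=se_mcc, se_auc=se_auc,
        n_repeats=len(per_repeat), skipped_folds=skipped,
    )


def repeated_cv(
    model: ModelSpec,
    X: np.ndarray | FeatureMatrix,
    y: Sequence[int],
    cv: CVConfig = CVConfig(),
    transform_hook: TransformHook | None = None,
) -> MetricsReport:
    """Repeated (stratified) k-fold evaluation of one model.

    ``transform_hook(X_train, y_train, X_test)`` runs inside every fold
    before scaling and fitting, so per-fold feature selection or encoder
    refits never see test rows.  Metrics are pooled over the folds of a
    repeat; means and standard errors are taken across repeats.
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(cv.seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=cv.repeats)
    per_repeat: list[MetricsReport] = []
    skipped = 0
    for rep_seed in repeat_seeds:
        splitter_cls = StratifiedKFold if cv.stratified else KFold
        splitter = splitter_cls(n_splits=cv.folds, shuffle=True, random_state=int(rep_seed))
        y_true_all, y_pred_all, y_score_all = [], [], []
        for train_idx, test_idx in splitter.split(values, y):
            y_tr, y_te = y[train_idx], y[test_idx]
            if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
                warnings.warn("fold missing a class; skipped", stacklevel=2)
                skipped += 1
                continue
            X_tr, X_te = values[train_idx], values[test_idx]
            if transform_hook is not None:
                X_tr, X_te = transform_hook(X_tr, y_tr, X_te)
            if model.needs_scaling:
                scaler = minmax_fit(X_tr)
                X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
            est = model.build(seed=int(rep_seed))
            est.fit(X_tr, y_tr)
            y_true_all.append(y_te)
            y_pred_all.append(est.predict(X_te))
            y_score_all.append(decision_scores(est, X_te))
        if not y_true_all:
            continue
        yt = np.concatenate(y_true_all)
        c = ConfusionCounts.from_predictions(yt, np.concatenate(y_pred_all))
        rep = metrics(c)
        _, auc_val = roc_auc(yt, np.concatenate(y_score_all))
        per_repeat.append(replace(rep, auc=auc_val))
    if not per_repeat:
        raise ValueError("every fold was skipped; check labels and stratification")
    return _summarize(per_repeat, skipped)


def make_cv_evaluator(
    model: ModelSpec, folds: int = 3, repeats: int = 1, seed: int = 0
) -> Callable[[np.ndarray, np.ndarray], float]:
    """Accuracy evaluator for IFS: a small, seeded repeated-CV run."""

    def evaluate(X: np.ndarray, y: np.ndarray) -> float:
        report = repeated_cv(model, X, y, CVConfig(folds=folds, repeats=repeats, seed=seed))
        return report.acc

    return evaluate


def grid_search(
    model: ModelSpec,
    X: np.ndarray | FeatureMatrix,
    y: Sequence[int],
    cv: CVConfig = CVConfig(folds=5, repeats=5, seed=0),
    grid: dict | None = None,
) -> tuple[dict, MetricsReport]:
    """Exhaustive search over the model's hyperparameter grid.

    Best point by mean CV accuracy; ties prefer fewer estimators, then a
    smaller learning rate, then declaration order.
    """
    import itertools as it

    grid = grid if grid is not None else model.grid
    if not grid:
        return {}, repeated_cv(model, X, y, cv)
    keys = list(grid)
    best: tuple | None = None
    for values_tuple in it.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, values_tuple))
        report = repeated_cv(model.with_params(**params), X, y, cv)
        key = (
            -report.acc,
            params.get("n_estimators", 0),
            params.get("learning_rate", 0.0),
        )
        if best is None or key < best[0]:
            best = (key, params, report)
    return best[1], best[2]
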