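"""End-to-end terminator prediction: encode, select, train, predict.

The default predictor reproduces the reference protocol: the group-8
feature set (parallel + series Pse5NC plus the 47-property positional
encoding), F-score ranking with incremental feature selection, and an
extreme-gradient-boosted tree classifier.  Everything that learns from
data — position weight models, the scaler, the ranking, the IFS prefix,
the classifier — is fitted on training sequences only and applied frozen
to new ones; cross-validation refits all of it inside every fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from .features import (
    FeatureMatrix,
    PositionWeightModel,
    TABLE_GROUPS,
    build_pwm,
    extract_group,
)
from .modeling import (
    CVConfig,
    MetricsReport,
    MinMaxNormalizer,
    ConfusionCounts,
    decision_scores,
    make_cv_evaluator,
    metrics,
    minmax_fit,
    model_spec,
    repeated_cv,
    roc_auc,
)
from .properties import PropertyTable, load_property_table
from .seqio import Dataset
from .selection import binomial_confidence, f_scores, incremental_selection

__all__ = [
    "PipelineConfig",
    "TerminatorPredictor",
    "cross_validate_pipeline",
    "PIPELINE_FORMAT_VERSION",
]

PIPELINE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to train a predictor reproducibly.

    ``group`` names a feature preset or lists family specs; ``selection``
    is ``"fscore"``, ``"binomial"`` or ``None`` (keep all features); the
    IFS settings bound the prefix search (every ``ifs_stride``-th prefix
    up to ``ifs_max_features``, each scored by a small seeded CV run).
    """

    group: str | tuple[str, ...] = "group8"
    lam: int = 5
    w: float = 0.1
    L_max: int = 82
    pwm_pseudocount: float = 0.25
    selection: str | None = "fscore"
    ifs_stride: int = 32
    ifs_max_features: int | None = 256
    ifs_folds: int = 3
    ifs_repeats: int = 1
    model: str = "xgb"
    model_base: str | None = None
    model_params: dict = field(default_factory=dict)
    seed: int = 0
    threshold: float = 0.5

    def families(self) -> tuple[str, ...]:
        if isinstance(self.group, str):
            return TABLE_GROUPS.get(self.group.lower(), (self.group,))
        return tuple(self.group)

    def pwm_ks(self) -> tuple[int, ...]:
        return tuple(
            int(s.split(":", 1)[1]) for s in self.families() if s.startswith("kpwm")
        )


class TerminatorPredictor:
    """Fitted feature-extraction + selection + classification pipeline."""

    def __init__(self, config: PipelineConfig = PipelineConfig(), table: PropertyTable | None = None):
        self.config = config
        self.table = table or load_property_table()
        self.spec = model_spec(config.model, base=config.model_base, **config.model_params)
        self.pwms: dict[int, PositionWeightModel] = {}
        self.selected_: np.ndarray | None = None
        self.feature_names_: list[str] | None = None
        self.scaler_: MinMaxNormalizer | None = None
        self.estimator_ = None
        self.ifs_ = None

    # -- fitting -----------------------------------------------------------

    def _extract(self, dataset: Dataset) -> FeatureMatrix:
        too_long = next((r for r in dataset if len(r) > self.config.L_max), None)
        if too_long is not None:
            raise ValueError(
                f"sequence {too_long.id!r} is {len(too_long)} bp, longer than the "
                f"configured L_max={self.config.L_max}"
            )
        return extract_group(
            dataset,
            self.config.families(),
            table=self.table,
            pwms=self.pwms or None,
            L_max=self.config.L_max,
            lam=self.config.lam,
            w=self.config.w,
        )

    def fit(self, train: Dataset) -> "TerminatorPredictor":
        cfg = self.config
        y = train.label_array()
        positives = train.subset([i for i, r in enumerate(train) if r.label == "positive"])
        for k in cfg.pwm_ks():
            self.pwms[k] = build_pwm(positives, k, pseudocount=cfg.pwm_pseudocount)
        X = self._extract(train)
        self.selected_, self.ifs_ = _select_features(X.values, y, cfg, X.feature_names)
        self.feature_names_ = [X.feature_names[j] for j in self.selected_]
        X_sel = X.values[:, self.selected_]
        if self.spec.needs_scaling:
            self.scaler_ = minmax_fit(X_sel)
            X_sel = self.scaler_.transform(X_sel)
        self.estimator_ = self.spec.build(seed=cfg.seed)
        self.estimator_.fit(X_sel, y)
        return self

    # -- prediction --------------------------------------------------------

    def _check_fitted(self) -> None:
        if self.estimator_ is None:
            raise RuntimeError("predictor is not fitted")

    def transform(self, dataset: Dataset) -> np.ndarray:
        self._check_fitted()
        X = self._extract(dataset).values[:, self.selected_]
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        return X

    def predict(self, dataset: Dataset) -> pd.DataFrame:
        """Prediction table: id, positive-class score, predicted label."""
        X = self.transform(dataset)
        scores = decision_scores(self.estimator_, X)
        labels = np.where(
            scores >= self.config.threshold, "positive", "negative"
        ) if hasattr(self.estimator_, "predict_proba") else np.where(
            self.estimator_.predict(X) == 1, "positive", "negative"
        )
        return pd.DataFrame({"id": dataset.ids, "score": scores, "label": labels})

    def evaluate(self, test: Dataset) -> tuple[pd.DataFrame, MetricsReport]:
        """Predict a labelled set and report Sn/Sp/Acc/MCC/AUC."""
        preds = self.predict(test)
        y = test.label_array()
        y_pred = (preds["label"] == "positive").to_numpy().astype(int)
        report = metrics(ConfusionCounts.from_predictions(y, y_pred))
        _, auc_val = roc_auc(y, preds["score"].to_numpy())
        return preds, replace(report, auc=auc_val)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self._check_fitted()
        joblib.dump(
            {
                "format_version": PIPELINE_FORMAT_VERSION,
                "config": self.config,
                "table": self.table,
                "pwms": self.pwms,
                "selected": self.selected_,
                "feature_names": self.feature_names_,
                "scaler": self.scaler_,
                "estimator": self.estimator_,
                "ifs": self.ifs_,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TerminatorPredictor":
        payload = joblib.load(path)
        if payload.get("format_version") != PIPELINE_FORMAT_VERSION:
            raise ValueError(
                f"unsupported pipeline file version {payload.get('format_version')!r}"
            )
        obj = cls(payload["config"], table=payload["table"])
        obj.pwms = payload["pwms"]
        obj.selected_ = payload["selected"]
        obj.feature_names_ = payload["feature_names"]
        obj.scaler_ = payload["scaler"]
        obj.estimator_ = payload["estimator"]
        obj.ifs_ = payload["ifs"]
        return obj


def _select_features(
    X: np.ndarray, y: np.ndarray, cfg: PipelineConfig, names: Sequence[str]
):
    if cfg.selection is None:
        return np.arange(X.shape[1]), None
    if cfg.selection == "fscore":
        ranking = f_scores(X, y)
    elif cfg.selection == "binomial":
        ranking = binomial_confidence(X, y)
    else:
        raise ValueError(f"unknown selection method {cfg.selection!r}")
    ranking = replace(ranking, feature_names=tuple(names))
    evaluator = make_cv_evaluator(
        model_spec(cfg.model, base=cfg.model_base, **cfg.model_params),
        folds=cfg.ifs_folds,
        repeats=cfg.ifs_repeats,
        seed=cfg.seed,
    )
    ifs = incremental_selection(
        X, y, ranking,
        evaluator=evaluator,
        stride=cfg.ifs_stride,
        max_features=cfg.ifs_max_features,
    )
    return ranking.order[: ifs.best_size].copy(), ifs


def cross_validate_pipeline(
    dataset: Dataset,
    config: PipelineConfig = PipelineConfig(),
    cv: CVConfig = CVConfig(),
) -> MetricsReport:
    """Repeated CV of the whole pipeline with per-fold refits.

    Position weight models, rankings, IFS prefixes and scalers are all
    re-fitted inside every training fold.  When the feature group
    contains no position-weight family the per-sequence encodings are
    computed once (they are pure functions of each sequence) and only the
    fold-dependent stages are refitted, which is equivalent and much
    faster.
    """
    y = dataset.label_array()
    predictor = TerminatorPredictor(config)
    if config.pwm_ks():
        return _cv_full_refit(dataset, y, config, cv, predictor.table)
    X = predictor._extract(dataset)

    def hook(X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray):
        sel, _ = _select_features(X_tr, y_tr, config, X.feature_names)
        return X_tr[:, sel], X_te[:, sel]

    return repeated_cv(predictor.spec, X, y, cv, transform_hook=hook)


def _cv_full_refit(dataset, y, config, cv, table) -> MetricsReport:
    from sklearn.model_selection import KFold, StratifiedKFold
    from .modeling import _summarize  # shared aggregation

    rng = np.random.default_rng(cv.seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=cv.repeats)
    per_repeat = []
    skipped = 0
    for rep_seed in repeat_seeds:
        splitter_cls = StratifiedKFold if cv.stratified else KFold
        splitter = splitter_cls(n_splits=cv.folds, shuffle=True, random_state=int(rep_seed))
        yt_all, yp_all, sc_all = [], [], []
        for train_idx, test_idx in splitter.split(np.zeros(len(y)), y):
            if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
                skipped += 1
                continue
            fold_cfg = replace(config, seed=int(rep_seed))
            model = TerminatorPredictor(fold_cfg, table=table).fit(
                dataset.subset(list(train_idx))
            )
            preds = model.predict(dataset.subset(list(test_idx)))
            yt_all.append(y[test_idx])
            yp_all.append((preds["label"] == "positive").to_numpy().astype(int))
            sc_all.append(preds["score"].to_numpy())
        if not yt_all:
            continue
        yt = np.concatenate(yt_all)
        rep = metrics(ConfusionCounts.from_predictions(yt, np.concatenate(yp_all)))
        _, auc_val = roc_auc(yt, np.concatenate(sc_all))
        per_repeat.append(replace(rep, auc=auc_val))
    if not per_repeat:
        raise ValueError("every fold was skipped; check labels")
    return _summarize(per_repeat, skipped)
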