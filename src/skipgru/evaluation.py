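"""Confusion-matrix metrics and the stratified k-fold protocol.

Metrics are the clinical-classification suite: accuracy, sensitivity
(recall on the diseased class), specificity, precision and F1, all as
percentages. Binary problems use the positive class (index 1); multiclass
problems macro-average per-class one-vs-rest values and are labeled as
such in every report. F1 is the harmonic mean of the reported precision
and sensitivity, so the identity F1 = 2PS/(P+S) holds for both averaging
modes by construction.

``kfold_evaluate`` runs the full in-fold pipeline with leakage isolation:
imputation and normalization are fitted on the training folds only and
applied to the held-out fold before the classifier sees it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, KFold

from .config import PipelineConfig
from .dataset import TabularDataset
from .model import predict, train
from .mpa import FeatureMask
from .preprocessing import Imputer, apply_minmax, fit_minmax
from .reports import register_report

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVResult",
    "confusion",
    "compute_metrics",
    "evaluate_predictions",
    "kfold_evaluate",
]

log = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "precision", "specificity", "f1")


@register_report
@dataclass
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN per class."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.tp.size

    @property
    def n_samples(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])


@register_report
@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    precision: float
    specificity: float
    f1: float
    averaging: str  # binary | macro

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@register_report
@dataclass
class CVResult:
    k: int
    folds: list = field(default_factory=list)  # MetricsReport per fold
    mean: dict = field(default_factory=dict)
    std: dict = field(default_factory=dict)
    best_fold: dict = field(default_factory=dict)
    seed: int = 0


def confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> ConfusionCounts:
    """One-vs-rest counts per class from paired label vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D, non-empty")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} contains indices outside [0, {n_classes})")
    M = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    n = y_true.size
    tp = np.diag(M).astype(int)
    fn = M.sum(axis=1) - tp
    fp = M.sum(axis=0) - tp
    tn = n - tp - fn - fp
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        log.warning("zero denominator in %s; reporting 0", what)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """The five-metric suite from confusion counts, as percentages."""
    if counts.n_samples < 1:
        raise ValueError("all counts are zero")
    if counts.n_classes == 2:
        tp, tn = int(counts.tp[1]), int(counts.tn[1])
        fp, fn = int(counts.fp[1]), int(counts.fn[1])
        acc = (tp + tn) / (tp + tn + fp + fn)
        sens = _safe_ratio(tp, tp + fn, "sensitivity")
        prec = _safe_ratio(tp, tp + fp, "precision")
        spec = _safe_ratio(tn, tn + fp, "specificity")
        averaging = "binary"
    else:
        n = counts.n_samples
        accs, senss, precs, specs = [], [], [], []
        for c in range(counts.n_classes):
            tp, tn = int(counts.tp[c]), int(counts.tn[c])
            fp, fn = int(counts.fp[c]), int(counts.fn[c])
            accs.append((tp + tn) / n)
            senss.append(_safe_ratio(tp, tp + fn, f"sensitivity[{c}]"))
            precs.append(_safe_ratio(tp, tp + fp, f"precision[{c}]"))
            specs.append(_safe_ratio(tn, tn + fp, f"specificity[{c}]"))
        acc = float(np.mean(accs))
        sens = float(np.mean(senss))
        prec = float(np.mean(precs))
        spec = float(np.mean(specs))
        averaging = "macro"
    f1 = _safe_ratio(2.0 * prec * sens, prec + sens, "f1")
    return MetricsReport(
        accuracy=100.0 * acc,
        sensitivity=100.0 * sens,
        precision=100.0 * prec,
        specificity=100.0 * spec,
        f1=100.0 * f1,
        averaging=averaging,
    )


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> MetricsReport:
    return compute_metrics(confusion(y_true, y_pred, n_classes))


def kfold_evaluate(
    dataset: TabularDataset,
    config: PipelineConfig | None = None,
    mask: FeatureMask | None = None,
) -> CVResult:
    """Stratified k-fold evaluation of the full in-fold pipeline.

    Per fold: fit imputation + normalization on the training folds, apply
    to the held-out fold (no row is dropped from a held-out fold), train a
    Skip-GRU on the masked features, predict, and score. An optional
    precomputed feature mask restricts the classifier's inputs.
    """
    config = config or PipelineConfig()
    config.validate()
    k = config.cv.k
    y = dataset.labels
    class_counts = np.bincount(y, minlength=dataset.n_classes)
    if config.cv.stratified and class_counts.min() < k:
        raise ValueError(
            f"stratified {k}-fold impossible: smallest class has "
            f"{class_counts.min()} members"
        )
    seed = config.stage_seed("cv")
    splitter_cls = StratifiedKFold if config.cv.stratified else KFold
    splitter = splitter_cls(n_splits=k, shuffle=True, random_state=seed)
    folds: list[MetricsReport] = []
    for fold_idx, (train_idx, test_idx) in enumerate(splitter.split(dataset.features, y)):
        train_ds = dataset.take_rows(train_idx)
        test_ds = dataset.take_rows(test_idx)
        imputer = Imputer(config.imputation).fit(train_ds)
        train_ds, _ = imputer.transform(train_ds)
        test_ds = imputer.apply_holdout(test_ds)
        params = fit_minmax(train_ds)
        train_ds = apply_minmax(train_ds, params)
        test_ds = apply_minmax(test_ds, params)
        model, _hist = train(
            train_ds, mask=mask, config=config.model,
            seed=config.stage_seed(f"train-fold{fold_idx}"),
        )
        sel = mask.indices() if mask is not None else np.arange(dataset.n_features)
        y_pred, _probs, _ = predict(test_ds.features[:, sel], model)
        folds.append(evaluate_predictions(test_ds.labels, y_pred, dataset.n_classes))
    mean = {m: float(np.mean([getattr(f, m) for f in folds])) for m in METRIC_NAMES}
    std = {m: float(np.std([getattr(f, m) for f in folds])) for m in METRIC_NAMES}
    best = max(folds, key=lambda f: f.accuracy)
    return CVResult(k=k, folds=folds, mean=mean, std=std,
                    best_fold=best.as_dict(), seed=config.seed)
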