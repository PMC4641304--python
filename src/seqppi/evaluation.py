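"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, k-fold CV.

Accuracy, sensitivity, precision and the Matthews correlation
coefficient are computed in exact integer/rational arithmetic from the
confusion counts; a metric whose denominator is zero is reported as
``None`` (undefined), never silently as 0.  AUC uses the Mann-Whitney
identity with ties counted as one half.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from . import wsrc
from .features import PairFeature
from .wsrc import DEFAULT_EPSILON, DEFAULT_SIGMA, WSRCModel

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "precision", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, labels: Sequence[int], predicted: Sequence[int]) -> "ConfusionCounts":
        labels = np.asarray(labels, dtype=int)
        predicted = np.asarray(predicted, dtype=int)
        if labels.shape != predicted.shape:
            raise ValueError("labels and predictions must align")
        return cls(
            tp=int(np.sum((labels == 1) & (predicted == 1))),
            tn=int(np.sum((labels == 0) & (predicted == 0))),
            fp=int(np.sum((labels == 0) & (predicted == 1))),
            fn=int(np.sum((labels == 1) & (predicted == 0))),
        )


@dataclass(frozen=True)
class MetricReport:
    """Metric values for one evaluated split; ``None`` marks undefined."""

    counts: ConfusionCounts
    accuracy: float | None
    sensitivity: float | None
    precision: float | None
    mcc: float | None
    auc: float | None = None

    def as_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "mcc": self.mcc,
            "auc": self.auc,
        }


def compute_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricReport:
    """Exact confusion-matrix metrics.

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

    All ratios are formed with exact rationals before conversion to
    float, so boundary cases (0, 1, -1) are exact.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else float(Fraction(num, den))

    accuracy = ratio(tp + tn, counts.total)
    sensitivity = ratio(tp, tp + fn)
    precision = ratio(tp, tp + fp)
    mcc_den = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    if mcc_den == 0:
        mcc = None
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den)
    return MetricReport(counts, accuracy, sensitivity, precision, mcc, auc)


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (Mann-Whitney; ties count one half)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def roc_points(labels: Sequence[int], scores: Sequence[float]) -> np.ndarray:
    """Stepwise ROC curve as an array of (fpr, tpr, threshold) rows."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr, thresholds])


@dataclass(frozen=True)
class PairPrediction:
    """Per-pair prediction row used in reports and TSV exports."""

    pair_id: tuple[str, str]
    label: int | None
    predicted: int
    score: float | None
    residual_neg: float
    residual_pos: float
    fold: int | None = None


@dataclass(frozen=True)
class CVResult:
    per_fold: list[MetricReport]
    mean: dict
    std: dict
    fold_assignment: dict
    predictions: list[PairPrediction]
    seed: int

    @property
    def k(self) -> int:
        return len(self.per_fold)


def _predict_pairs(model: WSRCModel, features: Sequence[PairFeature],
                   fold: int | None = None) -> list[PairPrediction]:
    rows = []
    for f in features:
        pred = wsrc.predict(model, f.vector)
        rows.append(
            PairPrediction(
                pair_id=f.pair_id,
                label=f.label,
                predicted=pred.predicted_class,
                score=pred.score,
                residual_neg=float(pred.residuals[0]),
                residual_pos=float(pred.residuals[-1]),
                fold=fold,
            )
        )
    return rows


def _report_from_rows(rows: Sequence[PairPrediction]) -> MetricReport:
    labels = [r.label for r in rows]
    predicted = [r.predicted for r in rows]
    counts = ConfusionCounts.from_predictions(labels, predicted)
    auc = None
    if len(set(labels)) == 2 and all(r.score is not None for r in rows):
        auc = roc_auc(labels, [r.score for r in rows])
    return compute_metrics(counts, auc)


def _aggregate(per_fold: Sequence[MetricReport]) -> tuple[dict, dict]:
    mean: dict = {}
    std: dict = {}
    for name in METRIC_NAMES:
        values = [getattr(r, name) for r in per_fold if getattr(r, name) is not None]
        if not values:
            mean[name] = None
            std[name] = None
            continue
        mean[name] = float(np.mean(values))
        # sample (n-1) standard deviation, as in "96.28 +/- 0.52" style reports
        std[name] = float(np.std(values, ddof=1)) if len(values) > 1 else None
    return mean, std


def assign_folds(
    features: Sequence[PairFeature], k: int, seed: int, stratify: bool = True
) -> np.ndarray:
    """Seeded fold assignment depending only on pair ids and labels.

    Features are put in canonical (sorted by pair id) order before the
    seeded shuffle, so the assignment is invariant to input order.
    Stratified assignment deals each class round-robin, continuing the
    deal across classes so overall fold sizes differ by at most one.
    """
    n = len(features)
    order = sorted(range(n), key=lambda i: (features[i].pair_id, features[i].label or 0, i))
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if stratify:
        offset = 0
        labels = [features[i].label for i in order]
        for cls in sorted(set(labels)):
            idx = np.array([order[j] for j in range(n) if labels[j] == cls])
            rng.shuffle(idx)
            for pos, i in enumerate(idx):
                folds[i] = (offset + pos) % k
            offset = (offset + idx.size) % k
    else:
        idx = np.array(order)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[i] = pos % k
    return folds


def cross_validate(
    features: Sequence[PairFeature],
    k: int = 5,
    seed: int = 0,
    sigma: float = DEFAULT_SIGMA,
    epsilon: float = DEFAULT_EPSILON,
    stratify: bool = True,
    weight_mode: str = "reciprocal",
) -> CVResult:
    """k-fold cross-validation of the full WSRC pipeline.

    The data are split into k near-equal folds (stratified by default);
    each fold is predicted by a model fitted on the other k-1.  Per-fold
    metrics and their mean and sample standard deviation are reported.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(features):
        raise ValueError("more folds than samples")
    if any(f.label is None for f in features):
        raise ValueError("cross-validation requires labelled pairs")

    folds = assign_folds(features, k, seed, stratify)
    per_fold: list[MetricReport] = []
    predictions: list[PairPrediction] = []
    for fold in range(k):
        train = [f for f, g in zip(features, folds) if g != fold]
        test = [f for f, g in zip(features, folds) if g == fold]
        train_labels = {f.label for f in train}
        if len(train_labels) < 2:
            raise ValueError(
                f"training split for fold {fold} contains one class; "
                "enable stratification or use fewer folds"
            )
        model = wsrc.fit(train, sigma=sigma, epsilon=epsilon, weight_mode=weight_mode)
        rows = _predict_pairs(model, test, fold)
        predictions.extend(rows)
        per_fold.append(_report_from_rows(rows))
        logger.info("fold %d/%d: %s", fold + 1, k, per_fold[-1].as_dict())

    mean, std = _aggregate(per_fold)
    assignment = {f.pair_id: int(g) for f, g in zip(features, folds)}
    return CVResult(per_fold, mean, std, assignment, predictions, seed)


@dataclass(frozen=True)
class TrainTestResult:
    report: MetricReport | None
    predictions: list[PairPrediction]
    model: WSRCModel


def train_test(
    train_features: Sequence[PairFeature],
    test_features: Sequence[PairFeature],
    sigma: float = DEFAULT_SIGMA,
    epsilon: float = DEFAULT_EPSILON,
    weight_mode: str = "reciprocal",
) -> TrainTestResult:
    """Fit once on a training set and evaluate on a separate test set.

    Supports the cross-dataset protocol: the test set may be entirely
    positive (metrics with zero denominators come back undefined) or
    unlabelled (predictions only, ``report`` is None).
    """
    if not test_features:
        raise ValueError("test set is empty")
    model = wsrc.fit(train_features, sigma=sigma, epsilon=epsilon, weight_mode=weight_mode)
    rows = _predict_pairs(model, test_features)
    report = None
    if all(f.label is not None for f in test_features):
        report = _report_from_rows(rows)
    return TrainTestResult(report, rows, model)
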