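"""Performance metrics and the n-fold cross-validation protocol.

With K+ succinylated and K- non-succinylated sites split into true/false
positives/negatives (tp, fn, tn, fp):

    sensitivity = tp / (tp + fn)          (true positive rate)
    specificity = tn / (tn + fp)          (true negative rate)
    accuracy    = (tp + tn) / (K+ + K-)
    MCC         = (tn*tp - fp*fn) / sqrt((tp+fn)(tp+fp)(tn+fn)(tn+fp))

MCC with a zero denominator is defined as 0 (the standard convention for
degenerate confusion tables).  The area under the ROC curve is computed
threshold-free from the real-valued SVM margin.

Cross-validation follows the usual five steps: randomly partition the data
into n roughly equal parts, hold one fold out, train on the rest, score
all metrics on the held-out fold, rotate over the n folds and average.
Partitioning is stratified so both classes appear in every fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

from .balance import LabeledDataset, balance as _balance
from .model import SVMParams, SuccinylationSVM

logger = logging.getLogger(__name__)

PAPER_FOLD_SETTINGS = (6, 8, 10)


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    """2x2 confusion table for {+1, -1} labels."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricSet:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "auc": self.auc,
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise EvaluationError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise EvaluationError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not set(np.unique(arr)) <= {-1, 1}:
            raise EvaluationError(f"{name} contains labels outside {{+1, -1}}")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
    )


def metrics(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, accuracy and MCC from a confusion table."""
    sens = c.tp / c.n_positive if c.n_positive else 0.0
    spec = c.tn / c.n_negative if c.n_negative else 0.0
    total = c.n_positive + c.n_negative
    acc = (c.tp + c.tn) / total if total else 0.0
    denom = (
        (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fn) * (c.tn + c.fp)
    )
    if denom == 0:
        logger.debug("MCC denominator zero; returning 0 by convention")
        mcc = 0.0
    else:
        mcc = (c.tn * c.tp - c.fp * c.fn) / np.sqrt(denom)
    return MetricSet(sensitivity=sens, specificity=spec, accuracy=acc, mcc=float(mcc))


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC curve points and trapezoidal AUC from real decision values.

    Ties in the scores are handled by the rank construction of the curve,
    so the AUC equals the normalized Mann-Whitney U statistic.  Raises on
    single-class truth, where the AUC is undefined.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(set(np.unique(y_true))) < 2:
        raise EvaluationError("AUC undefined for single-class truth")
    fpr, tpr, _ = _roc_curve(y_true, scores, pos_label=1)
    curve = np.column_stack([fpr, tpr])
    return curve, float(_trapezoid_auc(fpr, tpr))


@dataclass
class CVReport:
    """Per-fold and averaged cross-validation metrics."""

    n_folds: int
    seed: int
    per_fold: list[MetricSet]
    fold_sizes: list[int]
    repeats: int = 1
    balance_within_folds: bool = False
    balance_reports: list[dict] = field(default_factory=list)

    def _mean(self, attr: str) -> float:
        return float(np.mean([getattr(m, attr) for m in self.per_fold]))

    @property
    def mean_sensitivity(self) -> float:
        return self._mean("sensitivity")

    @property
    def mean_specificity(self) -> float:
        return self._mean("specificity")

    @property
    def mean_accuracy(self) -> float:
        return self._mean("accuracy")

    @property
    def mean_mcc(self) -> float:
        return self._mean("mcc")

    @property
    def mean_auc(self) -> float:
        return float(np.mean([m.auc for m in self.per_fold]))

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "seed": self.seed,
            "repeats": self.repeats,
            "balance_within_folds": self.balance_within_folds,
            "fold_sizes": self.fold_sizes,
            "per_fold": [m.as_dict() for m in self.per_fold],
            "means": {
                "sensitivity": self.mean_sensitivity,
                "specificity": self.mean_specificity,
                "accuracy": self.mean_accuracy,
                "mcc": self.mean_mcc,
                "auc": self.mean_auc,
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        """Table of per-fold and mean metrics."""
        header = (
            f"{'fold':>4}  {'Sensitivity':>11}  {'Specificity':>11}  "
            f"{'Accuracy':>8}  {'MCC':>7}  {'AUC':>7}"
        )
        rows = [f"{self.n_folds}-fold cross-validation (seed {self.seed})", header]
        for i, m in enumerate(self.per_fold, start=1):
            rows.append(
                f"{i:>4}  {m.sensitivity:>11.4f}  {m.specificity:>11.4f}  "
                f"{m.accuracy:>8.4f}  {m.mcc:>7.4f}  {m.auc:>7.4f}"
            )
        rows.append(
            f"{'mean':>4}  {self.mean_sensitivity:>11.4f}  "
            f"{self.mean_specificity:>11.4f}  {self.mean_accuracy:>8.4f}  "
            f"{self.mean_mcc:>7.4f}  {self.mean_auc:>7.4f}"
        )
        return "\n".join(rows)

    def plot_roc(self, curves, ax=None):
        """Plot per-fold ROC curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, curve in enumerate(curves, start=1):
            ax.plot(curve[:, 0], curve[:, 1], lw=1, label=f"fold {i}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(fontsize=8)
        return ax


def cross_validate(
    data: LabeledDataset,
    n_folds: int = 10,
    params: SVMParams | None = None,
    seed: int = 0,
    repeats: int = 1,
    balance_within_folds: bool = False,
    balance_kwargs: dict | None = None,
    return_curves: bool = False,
) -> CVReport | tuple[CVReport, list[np.ndarray]]:
    """Stratified n-fold cross-validation of the RBF SVM.

    One random partition is rotated over its n folds (Steps 1-5 of the
    protocol); ``repeats > 1`` re-partitions with fresh seeds and pools the
    folds.  With ``balance_within_folds`` the k-NN elimination runs on the
    training folds only, which avoids information leak from validation
    samples into the balancing step; the default (off) matches the
    balance-then-validate order of the original study.
    """
    if n_folds < 2:
        raise EvaluationError("n_folds must be >= 2")
    counts = (data.n_positive, data.n_negative)
    if min(counts) < n_folds:
        raise EvaluationError(
            f"each class needs >= {n_folds} samples for stratified "
            f"{n_folds}-fold CV, have {counts}"
        )
    params = params or SVMParams()
    per_fold: list[MetricSet] = []
    fold_sizes: list[int] = []
    curves: list[np.ndarray] = []
    balance_reports: list[dict] = []

    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        for train_idx, test_idx in skf.split(data.X, data.y):
            train_mask = np.zeros(data.n_samples, dtype=bool)
            train_mask[train_idx] = True
            train_set = data.subset(train_mask)
            if balance_within_folds:
                train_set, rep_bal = _balance(train_set, **(balance_kwargs or {}))
                balance_reports.append(rep_bal.to_dict())
            results = SuccinylationSVM(data=train_set, params=params).fit()
            X_test, y_test = data.X[test_idx], data.y[test_idx]
            scores = results.decision_function(X_test)
            y_pred = np.where(scores >= 0.0, 1, -1)
            m = metrics(confusion(y_test, y_pred))
            curve, m.auc = roc_auc(y_test, scores)
            per_fold.append(m)
            fold_sizes.append(len(test_idx))
            curves.append(curve)

    report = CVReport(
        n_folds=n_folds,
        seed=seed,
        per_fold=per_fold,
        fold_sizes=fold_sizes,
        repeats=repeats,
        balance_within_folds=balance_within_folds,
        balance_reports=balance_reports,
    )
    logger.info(
        "%d-fold CV (x%d): acc=%.4f mcc=%.4f auc=%.4f",
        n_folds, repeats, report.mean_accuracy, report.mean_mcc, report.mean_auc,
    )
    if return_curves:
        return report, curves
    return report
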