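"""Validation battery: stratified CV, sensitivity/specificity, geometric
mean, accuracy, and Cohen's kappa with a 95% confidence interval.

The screening task is imbalanced, so plain accuracy is a poor summary; the
battery therefore reports sensitivity S_T = tp/(tp+fn) and specificity
S_P = tn/(tn+fp) with "at risk" as the positive class, their geometric
mean G_M = sqrt(S_T * S_P), and Cohen's kappa

    k = (p_a - p_e) / (1 - p_e),

the chance-corrected agreement between the classifier's labels and the
expert reference, with a large-sample 95% CI (kappa +/- 1.96 * SE,
SE = sqrt(p_a (1 - p_a) / (n (1 - p_e)^2))).

Rates are expressed in percent to two decimals, matching clinical reporting
convention.  CV accuracy is pooled over folds (total correct / n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import classifier as _clf
from .errors import InvalidInputError

#: Label of the positive ("at risk") class.
POSITIVE_LABEL = -1


@dataclass
class ConfusionMatrix:
    """2x2 confusion counts with "at risk" as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_labels(cls, y_true, y_pred,
                    positive: int = POSITIVE_LABEL) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise InvalidInputError("label vectors must match in length")
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
        )

    def layout(self) -> str:
        """Confusion matrix as text, rows = expert label, cols = SVM output."""
        return (
            "                 predicted\n"
            "                 at-risk  normal\n"
            f"expert at-risk   {self.tp:7d} {self.fn:7d}\n"
            f"expert normal    {self.fp:7d} {self.tn:7d}\n"
        )


@dataclass
class EvaluationReport:
    """Rates (percent), kappa and its 95% CI for one confusion matrix."""

    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    geometric_mean: float
    accuracy: float
    kappa: float
    kappa_ci: tuple[float, float]
    p_a: float
    p_e: float

    def to_dict(self) -> dict:
        cm = self.confusion
        return {
            "tp": cm.tp, "fn": cm.fn, "tn": cm.tn, "fp": cm.fp,
            "sensitivity_pct": _r2(self.sensitivity),
            "specificity_pct": _r2(self.specificity),
            "geometric_mean_pct": _r2(self.geometric_mean),
            "accuracy_pct": _r2(self.accuracy),
            "kappa": round(self.kappa, 3) if not math.isnan(self.kappa) else float("nan"),
            "kappa_ci_low": round(self.kappa_ci[0], 3),
            "kappa_ci_high": round(self.kappa_ci[1], 3),
            "p_a": round(self.p_a, 4),
            "p_e": round(self.p_e, 4),
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [self.confusion.layout()]
        lines += [f"{k} = {v}" for k, v in d.items()
                  if k not in ("tp", "fn", "tn", "fp")]
        return "\n".join(lines)


def _r2(v: float) -> float:
    return round(v, 2) if not math.isnan(v) else float("nan")


def score(confusion: ConfusionMatrix) -> EvaluationReport:
    """All rates, kappa and its CI from one confusion matrix.

    An empty class leaves the affected rate undefined (NaN).
    """
    cm = confusion
    n = cm.total
    if n <= 0:
        raise InvalidInputError("empty confusion matrix")
    st = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else math.nan
    sp = 100.0 * cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else math.nan
    gm = math.sqrt(st * sp) if not (math.isnan(st) or math.isnan(sp)) else math.nan
    acc = 100.0 * (cm.tp + cm.tn) / n
    p_a = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fn) * (cm.tp + cm.fp)
           + (cm.tn + cm.fp) * (cm.tn + cm.fn)) / (n * n)
    if p_e < 1.0:
        kappa = (p_a - p_e) / (1.0 - p_e)
        se = math.sqrt(p_a * (1.0 - p_a) / (n * (1.0 - p_e) ** 2))
        ci = (kappa - 1.96 * se, kappa + 1.96 * se)
    else:
        kappa, ci = math.nan, (math.nan, math.nan)
    return EvaluationReport(confusion=cm, sensitivity=st, specificity=sp,
                            geometric_mean=gm, accuracy=acc, kappa=kappa,
                            kappa_ci=ci, p_a=p_a, p_e=p_e)


def stratified_kfold(labels, k: int, seed: int = 0) -> list[np.ndarray]:
    """k disjoint, label-stratified index folds (deterministic per seed).

    Per-fold class counts differ by at most one from exact
    proportionality; with 20 normal / 40 at-risk records and k = 5, every
    fold holds exactly 4 normal and 8 at-risk indices.
    """
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    if k > y.size:
        raise InvalidInputError("k may not exceed the number of records")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise InvalidInputError(
            f"stratified {k}-fold CV needs at least {k} records per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros((y.size, 1)), y)]


@dataclass
class CvResult:
    accuracy_pct: float
    fold_reports: list[EvaluationReport]
    pooled_report: EvaluationReport


def cross_validate(X, y, C: float = _clf.DEFAULT_C,
                   gamma: float = _clf.DEFAULT_GAMMA, k: int = 5,
                   seed: int = 0, weighted: bool = True) -> CvResult:
    """Stratified k-fold CV of the class-weighted SVM.

    For each fold the scaling transform and the class weights are
    recomputed on the training portion only; the held-out fold is then
    scored.  Pooled accuracy is total correct / n.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = stratified_kfold(y, k=k, seed=seed)
    all_idx = np.arange(y.size)
    fold_reports = []
    y_pred = np.zeros_like(y)
    for test in folds:
        train = np.setdiff1d(all_idx, test)
        model = _clf.fit(X[train], y[train], C=C, gamma=gamma,
                         weighted=weighted)
        pred = model.predict(X[test])
        y_pred[test] = pred
        fold_reports.append(score(ConfusionMatrix.from_labels(y[test], pred)))
    pooled = score(ConfusionMatrix.from_labels(y, y_pred))
    return CvResult(accuracy_pct=pooled.accuracy,
                    fold_reports=fold_reports, pooled_report=pooled)


def evaluate_split(X_train, y_train, X_test, y_test,
                   C: float = _clf.DEFAULT_C, gamma: float = _clf.DEFAULT_GAMMA,
                   weighted: bool = True):
    """Fit on the training set; score predictions on both sets.

    Returns
    -------
    (model, train_report, test_report)
    """
    model = _clf.fit(X_train, y_train, C=C, gamma=gamma, weighted=weighted)
    tr = score(ConfusionMatrix.from_labels(y_train, model.predict(X_train)))
    te = score(ConfusionMatrix.from_labels(y_test, model.predict(X_test)))
    return model, tr, te
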