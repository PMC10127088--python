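"""SVM training, grid search, cross-validation and the binary metric suite.

The classifier contract is the kernel/C/gamma surface: an exhaustive
grid search scored by mean stratified k-fold accuracy on a fixed seeded
partition (ties prefer smaller C, then smaller gamma), with the winning
pair refit on the full training set.  The margin optimization itself is
delegated to libsvm via scikit-learn.

Metrics are computed from the confusion matrix at the default decision
threshold (decision-function sign): sensitivity Sn = TP/(TP+FN),
specificity Sp = TN/(TN+FP), accuracy, precision, F1 and Matthews
correlation coefficient, plus a ROC curve swept over the continuous
decision score with trapezoidal AUC.  Metrics with an undefined
denominator are reported as 0 and flagged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: canonical log-spaced grids (powers of 4)
DEFAULT_C_GRID = tuple(float(2.0**e) for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0**e) for e in range(-15, 4, 2))


@dataclass
class SvmConfig:
    """Kernel/C/gamma surface of the SVM plus the search grid and seed."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: Union[float, str] = "scale"
    C_grid: Sequence[float] = DEFAULT_C_GRID
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear", "poly", "polynomial", "sigmoid"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("numeric gamma must be positive")

    def estimator(self, C: Optional[float] = None, gamma=None) -> SVC:
        kernel = "poly" if self.kernel == "polynomial" else self.kernel
        return SVC(
            kernel=kernel,
            C=self.C if C is None else C,
            gamma=self.gamma if gamma is None else gamma,
            random_state=self.seed,
        )


def _metric_or_zero(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Closed-form binary metrics from confusion counts.

    Undefined-denominator metrics are 0 and listed under ``"flags"``.
    """
    flags: list[str] = []
    n = tp + fp + tn + fn
    sn = _metric_or_zero(tp, tp + fn, "sn", flags)
    sp = _metric_or_zero(tn, tn + fp, "sp", flags)
    acc = _metric_or_zero(tp + tn, n, "acc", flags)
    precision = _metric_or_zero(tp, tp + fp, "precision", flags)
    f1 = _metric_or_zero(2 * precision * sn, precision + sn, "f1", flags)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _metric_or_zero(float(tp) * tn - float(fp) * fn, mcc_den, "mcc", flags)
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sn": sn, "sp": sp, "acc": acc,
        "precision": precision, "f1": f1, "mcc": mcc,
        "flags": flags,
    }


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve by sweeping the continuous score, high to low.

    Tied scores collapse to a single operating point, so the curve is the
    convex piecewise-linear path standard trapezoidal AUC integrates.
    Returns (fpr, tpr) arrays starting at (0,0) and ending at (1,1).
    """
    y_true = np.asarray(y_true).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    P = int(np.sum(y_true == 1))
    N = int(np.sum(y_true == 0))
    if P == 0 or N == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied-score run
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / P]
    fpr = np.r_[0.0, fps[distinct] / N]
    return fpr, tpr


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


@dataclass
class EvalReport:
    """Confusion counts, threshold metrics, ROC points and AUC."""

    tp: int
    fp: int
    tn: int
    fn: int
    sn: float
    sp: float
    acc: float
    mcc: float
    precision: float
    f1: float
    roc: list[tuple[float, float]]
    auc: float
    flags: list[str] = field(default_factory=list)
    per_fold: Optional[list["EvalReport"]] = None
    mean_metrics: Optional[dict] = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def metrics(self) -> dict:
        return {
            "sn": self.sn, "sp": self.sp, "acc": self.acc, "mcc": self.mcc,
            "precision": self.precision, "f1": self.f1, "auc": self.auc,
        }

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            **self.metrics(), "flags": self.flags,
        }
        if self.mean_metrics is not None:
            d["fold_mean"] = self.mean_metrics
        if self.per_fold is not None:
            d["per_fold"] = [f.metrics() for f in self.per_fold]
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def report_from_scores(y_true, scores, threshold: float = 0.0) -> EvalReport:
    """Build an EvalReport from continuous decision scores.

    Predictions are score > threshold (the solver's default 0 boundary).
    """
    y_true = np.asarray(y_true).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    pred = (scores > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    m = metrics_from_counts(tp, fp, tn, fn)
    fpr, tpr = roc_points(y_true, scores)
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sn=m["sn"], sp=m["sp"], acc=m["acc"], mcc=m["mcc"],
        precision=m["precision"], f1=m["f1"],
        roc=list(zip(fpr.tolist(), tpr.tolist())),
        auc=auc_trapezoid(fpr, tpr),
        flags=m["flags"],
    )


def evaluate(model, X, y) -> EvalReport:
    """Evaluate a trained model on (X, y) with the full metric suite."""
    X = np.asarray(X, dtype=float)
    scores = model.decision_function(X)
    return report_from_scores(y, scores)


def train_svm(
    X, y, cfg: SvmConfig, folds: int = 10
) -> tuple[SVC, tuple[float, float], float]:
    """Grid-search (C, gamma) by seeded stratified k-fold accuracy.

    Every candidate is scored on the same fold partition; ties prefer
    smaller C, then smaller gamma.  Returns the model refit on all of
    (X, y), the chosen pair, and its CV accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training requires two classes")
    if not cfg.C_grid or (cfg.kernel != "linear" and not cfg.gamma_grid):
        raise ValueError("empty hyperparameter grid")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(X, y))

    gamma_grid = cfg.gamma_grid if cfg.kernel != "linear" else [cfg.gamma]
    best_acc, best_pair = -1.0, None
    for C in sorted(cfg.C_grid):
        for gamma in sorted(gamma_grid, key=lambda g: (isinstance(g, str), g)):
            fold_acc = []
            for tr, te in splits:
                clf = cfg.estimator(C=C, gamma=gamma)
                clf.fit(X[tr], y[tr])
                fold_acc.append(float(np.mean(clf.predict(X[te]) == y[te])))
            acc = float(np.mean(fold_acc))
            if acc > best_acc + 1e-12:  # strict improvement keeps smaller C/gamma on ties
                best_acc, best_pair = acc, (C, gamma)
    assert best_pair is not None
    model = cfg.estimator(C=best_pair[0], gamma=best_pair[1])
    model.fit(X, y)
    return model, best_pair, best_acc


def cross_validate(X, y, cfg: SvmConfig, folds: int = 10, seed: Optional[int] = None) -> EvalReport:
    """Stratified k-fold CV with per-fold reports, pooled counts and fold means.

    The returned report's confusion counts pool all held-out predictions;
    ``mean_metrics`` holds the across-fold mean of each metric (the
    conventional k-fold estimate) and ``per_fold`` the individual fold
    reports.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if seed is None:
        seed = cfg.seed
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold: list[EvalReport] = []
    pooled_scores = np.empty(len(y))
    for tr, te in skf.split(X, y):
        clf = cfg.estimator()
        clf.fit(X[tr], y[tr])
        scores = clf.decision_function(X[te])
        pooled_scores[te] = scores
        per_fold.append(report_from_scores(y[te], scores))
    pooled = report_from_scores(y, pooled_scores)
    keys = ("sn", "sp", "acc", "mcc", "precision", "f1", "auc")
    pooled.mean_metrics = {
        k: float(np.mean([f.metrics()[k] for f in per_fold])) for k in keys
    }
    pooled.per_fold = per_fold
    return pooled
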