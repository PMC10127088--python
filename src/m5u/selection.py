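"""Two-step feature optimization: importance ranking + incremental selection.

Step one ranks the fused physicochemical features by one of four
importance measures: one-way ANOVA F statistic, the classical
feature-selection F-score, or gain importance from a gradient-boosted
tree ensemble (LightGBM or XGBoost backend).  Step two is accuracy-based
incremental feature selection (IFS): growing prefixes of the ranked list
are evaluated by stratified k-fold cross-validation with a fixed
classifier, and the smallest prefix attaining the maximum mean accuracy
is kept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.model_selection import StratifiedKFold

RankMethod = str  # {"anova", "fscore", "gbdt_lightgbm", "gbdt_xgboost"}


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def _check_two_class(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("ranking requires samples from two classes")
    return y


@dataclass
class FeatureRanking:
    """Feature names in descending importance with matching scores."""

    method: RankMethod
    names: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.names) != len(self.scores):
            raise ValueError("names and scores length mismatch")
        finite = self.scores[np.isfinite(self.scores)]
        if finite.size and np.any(np.diff(self.scores[np.isfinite(self.scores)]) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rank": np.arange(1, len(self.names) + 1),
             "feature": self.names, "score": self.scores}
        )


def _ranked(method: str, names: list[str], scores: np.ndarray) -> FeatureRanking:
    # stable argsort keeps original column order on ties
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(method, [names[i] for i in order], scores[order])


def rank_anova(X, y) -> FeatureRanking:
    """Rank by the per-feature one-way ANOVA F statistic between classes.

    Constant features (zero between- and within-class variance) score 0
    and fall to the bottom.
    """
    M, names = _as_matrix(X)
    y = _check_two_class(y)
    from sklearn.feature_selection import f_classif

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, _ = f_classif(M, y)
    f_stat = np.where(np.isfinite(f_stat), f_stat, 0.0)
    return _ranked("anova", names, f_stat)


def rank_fscore(X, y) -> FeatureRanking:
    """Rank by the classical feature-selection F-score.

    score = ((m+ - m)^2 + (m- - m)^2) / (var+ + var-) with sample
    (ddof=1) variances.  A zero denominator gives 0 when the class means
    coincide and +inf when they differ (a perfect separator).
    """
    M, names = _as_matrix(X)
    y = _check_two_class(y)
    pos, neg = M[y == 1], M[y == 0]
    m, mp, mn = M.mean(axis=0), pos.mean(axis=0), neg.mean(axis=0)
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = num / den
    score = np.where(den == 0, np.where(num == 0, 0.0, np.inf), score)
    return _ranked("fscore", names, score)


def rank_tree_importance(X, y, backend: str = "gbdt_lightgbm", seed: int = 0,
                         n_estimators: int = 100) -> FeatureRanking:
    """Rank by gain importance from a gradient-boosted tree ensemble.

    ``backend`` selects LightGBM or XGBoost; both are fit single-threaded
    with a fixed seed so the ranking is reproducible.  Ties keep the
    original column order.
    """
    M, names = _as_matrix(X)
    y = _check_two_class(y)
    if backend == "gbdt_lightgbm":
        try:
            import lightgbm as lgb
        except ImportError as e:  # pragma: no cover
            raise RuntimeError(
                "LightGBM backend unavailable; use method 'anova' or 'fscore'"
            ) from e
        clf = lgb.LGBMClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1,
            deterministic=True, force_row_wise=True, verbose=-1,
        )
        clf.fit(M, y)
        gains = clf.booster_.feature_importance(importance_type="gain")
    elif backend == "gbdt_xgboost":
        try:
            import xgboost as xgb
        except ImportError as e:  # pragma: no cover
            raise RuntimeError(
                "XGBoost backend unavailable; use method 'anova' or 'fscore'"
            ) from e
        clf = xgb.XGBClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1,
            importance_type="total_gain", verbosity=0,
        )
        clf.fit(M, y)
        gains = clf.feature_importances_
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return _ranked(backend, names, np.asarray(gains, dtype=float))


def rank_features(X, y, method: RankMethod = "gbdt_lightgbm", seed: int = 0) -> FeatureRanking:
    """Dispatch to one of the four ranking methods by name."""
    if method == "anova":
        return rank_anova(X, y)
    if method == "fscore":
        return rank_fscore(X, y)
    if method in ("gbdt_lightgbm", "gbdt_xgboost"):
        return rank_tree_importance(X, y, backend=method, seed=seed)
    raise ValueError(f"unknown ranking method {method!r}")


@dataclass
class SelectionResult:
    """Outcome of accuracy-based incremental feature selection."""

    ranking: FeatureRanking
    prefix_sizes: list[int]
    prefix_acc: list[float]
    best_size: int
    best_features: list[str]

    def __post_init__(self) -> None:
        best = max(self.prefix_acc)
        idx = self.prefix_acc.index(best)  # first (= smallest prefix) maximum
        if self.prefix_sizes[idx] != self.best_size:
            raise ValueError("best_size is not the smallest argmax prefix")
        if self.best_features != self.ranking.names[: self.best_size]:
            raise ValueError("best_features must be the leading ranked names")

    def to_frame(self) -> pd.DataFrame:
        acc = dict(zip(self.prefix_sizes, self.prefix_acc))
        df = self.ranking.to_frame()
        df["cv_accuracy_at_prefix"] = [acc.get(r, np.nan) for r in df["rank"]]
        return df

    def summary(self) -> dict:
        return {
            "method": self.ranking.method,
            "best_size": self.best_size,
            "best_cv_accuracy": max(self.prefix_acc),
            "n_features": len(self.ranking.names),
            "best_features": self.best_features,
        }

    def save(self, tsv_path: str | Path, json_path: Optional[str | Path] = None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=2))


def incremental_feature_selection(
    ranking: FeatureRanking,
    X,
    y,
    classifier: BaseEstimator,
    folds: int = 10,
    step: int = 1,
    seed: int = 0,
) -> SelectionResult:
    """Evaluate growing ranked prefixes under CV; keep the smallest argmax.

    The same seeded stratified fold partition is reused for every prefix
    so accuracies are comparable across prefix sizes.  Prefix sizes are
    step, 2*step, ... plus the full feature count.
    """
    M, names = _as_matrix(X)
    y = _check_two_class(y)
    if set(ranking.names) != set(names):
        raise ValueError("ranking does not cover the matrix columns")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    class_counts = np.bincount(y.astype(int))
    if folds > class_counts[class_counts > 0].min():
        raise ValueError(f"folds={folds} exceeds the smallest class count")
    if step < 1:
        raise ValueError("step must be >= 1")

    col = {n: i for i, n in enumerate(names)}
    ordered = M[:, [col[n] for n in ranking.names]]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(ordered, y))

    sizes = list(range(step, ordered.shape[1] + 1, step))
    if not sizes or sizes[-1] != ordered.shape[1]:
        sizes.append(ordered.shape[1])

    accs = []
    for size in sizes:
        Xp = ordered[:, :size]
        fold_acc = []
        for tr, te in splits:
            clf = clone(classifier)
            clf.fit(Xp[tr], y[tr])
            fold_acc.append(float(np.mean(clf.predict(Xp[te]) == y[te])))
        accs.append(float(np.mean(fold_acc)))

    best_idx = int(np.argmax(accs))  # argmax returns the first = smallest prefix
    best_size = sizes[best_idx]
    return SelectionResult(
        ranking=ranking,
        prefix_sizes=sizes,
        prefix_acc=accs,
        best_size=best_size,
        best_features=ranking.names[:best_size],
    )
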