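"""Recursive feature elimination with group-aware cross-validation.

A linear estimator is fitted repeatedly; at each round the fraction of
remaining features with the smallest absolute weights is dropped, and the
cross-validated balanced accuracy is recorded at every subset size.  Folds
are grouped by case so that pixels of one patient never straddle the
train/validation split.  The returned subset size maximizes the mean CV
balanced accuracy, with ties broken toward the smaller subset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler

from .classify import make_estimator, quiet_fit
from .features.matrix import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["SelectionResult", "rfe_cv"]


@dataclass
class SelectionResult:
    """Outcome of RFE-CV: a ranking, the chosen subset, and the CV curve."""

    ranking: list[str]            # best-first
    selected: list[str]
    cv_scores: dict[int, float]   # subset size -> mean CV balanced accuracy
    estimator_kind: str
    n_folds_used: int = 0
    fold_scores: dict[int, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert set(self.selected) <= set(self.ranking)


def _schedule(n_features: int, step: float | int) -> list[int]:
    """Subset sizes visited, from all features down to 1."""
    sizes = [n_features]
    n = n_features
    while n > 1:
        k = max(1, int(step * n)) if isinstance(step, float) and step < 1 else max(1, int(step))
        n = max(1, n - k)
        sizes.append(n)
    return sizes


def _eliminate(X, y, sizes, estimator_factory, score_on=None):
    """One elimination pass; optionally score each size on held-out data.

    Returns (scores per size or None, elimination order: feature column
    indices from first-dropped to last, final-fit |weights| of survivors).
    """
    active = np.arange(X.shape[1])
    order: list[int] = []
    scores = {}
    last_weights = None
    Xv, yv = (None, None) if score_on is None else score_on
    for pos, size in enumerate(sizes):
        est = estimator_factory()
        with quiet_fit():
            est.fit(X[:, active], y)
        w = np.abs(np.ravel(est.coef_))
        last_weights = w
        if score_on is not None:
            with warnings.catch_warnings():
                # a validation fold may contain one class only; its balanced
                # accuracy degenerates to that class's recall, which is fine
                warnings.simplefilter("ignore", UserWarning)
                scores[size] = balanced_accuracy_score(yv, est.predict(Xv[:, active]))
        if pos + 1 < len(sizes):
            n_drop = active.size - sizes[pos + 1]
            drop_local = np.argsort(w, kind="stable")[:n_drop]
            order.extend(active[np.sort(drop_local)])
            active = np.delete(active, drop_local)
    return (scores if score_on is not None else None), order, active, last_weights


def rfe_cv(
    fm: FeatureMatrix,
    estimator_kind: str = "svm",
    n_folds: int = 10,
    step: float | int = 0.1,
    seed: int = 0,
) -> SelectionResult:
    """Select the feature subset maximizing group-CV balanced accuracy."""
    X = fm.features()
    y = fm.labels()
    groups = fm.groups()
    if np.unique(y).size < 2:
        raise ValueError("rfe_cv requires both classes present")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    names = fm.feature_columns
    n_groups = np.unique(groups).size
    folds = min(n_folds, n_groups)
    if folds < n_folds:
        logger.warning("only %d groups; using %d-fold group CV", n_groups, folds)
    if folds < 2:
        raise ValueError("group-aware CV needs >= 2 groups (cases)")

    sizes = _schedule(X.shape[1], step)
    factory = lambda: make_estimator(estimator_kind, seed=seed, fast=True)

    fold_scores: dict[int, list[float]] = {s: [] for s in sizes}
    gkf = GroupKFold(n_splits=folds)
    for tr, va in gkf.split(X, y, groups):
        if np.unique(y[tr]).size < 2:
            continue
        scaler = StandardScaler().fit(X[tr])
        Xtr, Xva = scaler.transform(X[tr]), scaler.transform(X[va])
        scores, _, _, _ = _eliminate(Xtr, y[tr], sizes, factory, score_on=(Xva, y[va]))
        for s, v in scores.items():
            fold_scores[s].append(float(v))

    mean_scores = {s: float(np.mean(v)) for s, v in fold_scores.items() if v}
    if not mean_scores:
        raise ValueError("no usable CV folds")
    best = max(mean_scores, key=lambda s: (mean_scores[s], -s))

    # final elimination pass on all rows for the ranking and the subset
    scaler = StandardScaler().fit(X)
    _, order, survivors, w = _eliminate(scaler.transform(X), y, sizes, factory)
    survivors_ranked = [survivors[i] for i in np.argsort(-w, kind="stable")]
    ranking_idx = survivors_ranked + list(reversed(order))
    ranking = [names[i] for i in ranking_idx]
    selected = sorted(ranking[:best])
    return SelectionResult(
        ranking=ranking,
        selected=selected,
        cv_scores=mean_scores,
        estimator_kind=estimator_kind,
        n_folds_used=folds,
        fold_scores=fold_scores,
    )
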