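"""Linear classifiers for the pixel-cellularity problem.

Two estimator kinds mirror the training procedures compared by the
pipeline: a soft-margin support vector machine (hinge loss, maximal margin)
and a linear model trained by mini-batch stochastic gradient descent on the
hinge loss with an inverse-scaling learning rate.  Both use
inverse-frequency class weights because the high-/low-cellularity classes
are generally unbalanced.  Prediction runs block-wise: the tumor pixels of
a new case are split into blocks of 400 and every point of each block is
classified.
"""

from __future__ import annotations

import json
import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import accuracy_score, balanced_accuracy_score
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .features.matrix import BLOCK_SIZE, FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "MiniBatchSGDHinge",
    "make_estimator",
    "TrainedClassifier",
    "train_classifier",
    "predict_blocks",
    "cross_validate_10fold",
]


@contextmanager
def quiet_fit():
    """SGD runs a fixed epoch budget by design; the convergence warning is
    expected and suppressed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


@dataclass(frozen=True)
class ClassifierConfig:
    svm_C: float = 1.0
    svm_kernel: str = "linear"
    svm_max_iter: int = 10000
    sgd_alpha: float = 1e-4
    sgd_eta0: float = 0.01
    sgd_epochs: int = 100
    sgd_batch_size: int = 32


class MiniBatchSGDHinge(BaseEstimator, ClassifierMixin):
    """Hinge-loss linear model fitted by mini-batch SGD.

    Shuffled mini-batches of ``batch_size`` examples per epoch, updated via
    :meth:`SGDClassifier.partial_fit` so the inverse-scaling learning rate
    decays continuously across batches.  Class weights are the explicit
    inverse-frequency dict ('balanced' is not supported with partial_fit).
    """

    def __init__(self, batch_size=32, epochs=100, alpha=1e-4, eta0=0.01, random_state=0):
        self.batch_size = batch_size
        self.epochs = epochs
        self.alpha = alpha
        self.eta0 = eta0
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need two classes")
        weights = {c: y.size / (classes.size * n) for c, n in zip(classes, counts)}
        self._clf = SGDClassifier(
            loss="hinge",
            learning_rate="invscaling",
            eta0=self.eta0,
            alpha=self.alpha,
            class_weight=weights,
            random_state=self.random_state,
            shuffle=False,
        )
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        for _ in range(self.epochs):
            perm = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                self._clf.partial_fit(X[idx], y[idx], classes=classes)
        self.classes_ = self._clf.classes_
        return self

    @property
    def coef_(self):
        return self._clf.coef_

    @property
    def intercept_(self):
        return self._clf.intercept_

    def decision_function(self, X):
        return self._clf.decision_function(X)

    def predict(self, X):
        return self._clf.predict(X)


def make_estimator(
    kind: str,
    seed: int = 0,
    config: ClassifierConfig | None = None,
    fast: bool = False,
):
    """Estimator factory; ``fast`` picks the cheaper SGD variant used inside
    the feature-elimination loops (plain per-sample SGD instead of
    mini-batches — same loss, schedule and class weighting)."""
    cfg = config or ClassifierConfig()
    if kind == "svm":
        if cfg.svm_kernel == "linear":
            return LinearSVC(
                C=cfg.svm_C,
                class_weight="balanced",
                dual=False,
                max_iter=cfg.svm_max_iter,
            )
        return SVC(
            C=cfg.svm_C, kernel=cfg.svm_kernel, class_weight="balanced",
            random_state=seed,
        )
    if kind == "sgd":
        if fast:
            return SGDClassifier(
                loss="hinge",
                learning_rate="invscaling",
                eta0=cfg.sgd_eta0,
                alpha=cfg.sgd_alpha,
                max_iter=cfg.sgd_epochs,
                tol=1e-4,
                class_weight="balanced",
                random_state=seed,
            )
        return MiniBatchSGDHinge(
            batch_size=cfg.sgd_batch_size,
            epochs=cfg.sgd_epochs,
            alpha=cfg.sgd_alpha,
            eta0=cfg.sgd_eta0,
            random_state=seed,
        )
    raise ValueError(f"unknown estimator kind {kind!r} (use 'svm' or 'sgd')")


@dataclass
class TrainedClassifier:
    """A fitted classifier plus everything needed to reuse it.

    Standardization parameters are fitted on the training rows only and are
    applied to any matrix the model later predicts on.
    """

    kind: str
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    estimator: object
    config: ClassifierConfig
    seed: int

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._standardize(X)), int)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.decision_function(self._standardize(X))

    def to_json(self) -> str:
        est = self.estimator
        payload = {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "coef": np.ravel(est.coef_).tolist(),
            "intercept": float(np.ravel(est.intercept_)[0]),
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrainedClassifier":
        d = json.loads(text)
        model = _LinearStub(np.asarray(d["coef"]), d["intercept"])
        return cls(
            kind=d["kind"],
            feature_names=list(d["feature_names"]),
            scaler_mean=np.asarray(d["scaler_mean"]),
            scaler_scale=np.asarray(d["scaler_scale"]),
            estimator=model,
            config=ClassifierConfig(),
            seed=int(d["seed"]),
        )


class _LinearStub:
    """Deserialized linear decision function."""

    def __init__(self, coef: np.ndarray, intercept: float):
        self.coef_ = coef.reshape(1, -1)
        self.intercept_ = np.array([intercept])

    def decision_function(self, X):
        return X @ self.coef_.ravel() + self.intercept_[0]

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


def train_classifier(
    fm: FeatureMatrix,
    kind: str,
    config: ClassifierConfig | None = None,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> TrainedClassifier:
    """Standardize (training statistics only) and fit one estimator."""
    cfg = config or ClassifierConfig()
    names = feature_names if feature_names is not None else fm.feature_columns
    missing = [n for n in names if n not in fm.frame.columns]
    if missing:
        raise KeyError(f"feature columns missing from matrix: {missing}")
    X = fm.frame[names].to_numpy(float)
    y = fm.labels()
    if np.unique(y).size < 2:
        raise ValueError("training labels are degenerate (single class)")
    scaler = StandardScaler().fit(X)
    scale = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
    est = make_estimator(kind, seed=seed, config=cfg)
    with quiet_fit():
        est.fit((X - scaler.mean_) / scale, y)
    return TrainedClassifier(
        kind=kind,
        feature_names=list(names),
        scaler_mean=scaler.mean_,
        scaler_scale=scale,
        estimator=est,
        config=cfg,
        seed=seed,
    )


def predict_blocks(model: TrainedClassifier, fm: FeatureMatrix) -> np.ndarray:
    """Per-pixel predictions, processed in blocks of 400 rows.

    Returns one label per row of ``fm`` in row order; the index columns of
    the matrix map each prediction back to its voxel.
    """
    missing = [n for n in model.feature_names if n not in fm.frame.columns]
    if missing:
        raise KeyError(f"feature columns missing from matrix: {missing}")
    X = fm.frame[model.feature_names].to_numpy(float)
    out = np.empty(len(X), dtype=int)
    for start in range(0, len(X), BLOCK_SIZE):
        sl = slice(start, start + BLOCK_SIZE)
        out[sl] = model.predict_matrix(X[sl])
    return out


def cross_validate_10fold(
    fm: FeatureMatrix,
    kind: str,
    seed: int = 0,
    n_folds: int = 10,
    config: ClassifierConfig | None = None,
    feature_names: list[str] | None = None,
):
    """Group-stratified k-fold CV scores (accuracy, balanced accuracy).

    Folds are formed at the case level; with fewer than ``n_folds`` cases
    the largest feasible fold count is used with a warning.
    """
    groups = fm.groups()
    n_groups = np.unique(groups).size
    folds = min(n_folds, n_groups)
    if folds < n_folds:
        logger.warning(
            "only %d cases; falling back to %d-fold case-level CV", n_groups, folds
        )
    if folds < 2:
        raise ValueError("case-level CV needs >= 2 cases")
    names = feature_names if feature_names is not None else fm.feature_columns
    X = fm.frame[names].to_numpy(float)
    y = fm.labels()
    rows = []
    for i, (tr, va) in enumerate(GroupKFold(n_splits=folds).split(X, y, groups)):
        sub = FeatureMatrix(fm.frame.iloc[tr].reset_index(drop=True))
        model = train_classifier(sub, kind, config=config, seed=seed, feature_names=names)
        pred = model.predict_matrix(X[va])
        rows.append(
            {
                "fold": i,
                "accuracy": float(accuracy_score(y[va], pred)),
                "balanced_accuracy": float(balanced_accuracy_score(y[va], pred)),
                "n_rows": int(va.size),
            }
        )
    return rows
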