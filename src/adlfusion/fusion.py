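"""Early and late (probability-stacking) fusion of inertial and vision features.

Early fusion concatenates the two wrists' inertial features with the windowed
vision features and trains a single classifier. Late fusion trains one base
classifier per modality (defaults: a random forest on the inertial block and an
L2 logistic regression on the vision block), appends each base model's
per-class probabilities to its own feature block, concatenates the augmented
blocks, and trains a meta classifier on the result.

Both are scikit-learn estimators: they take a single feature matrix ``X``
whose first ``n_imu_features`` columns are the inertial block and the rest the
vision block, so they clone, pipeline and cross-validate like any other
classifier.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.utils.validation import check_is_fitted

from .types import FusedInstance

__all__ = [
    "default_imu_classifier",
    "default_vision_classifier",
    "default_meta_classifier",
    "EarlyFusionClassifier",
    "LateFusionClassifier",
    "early_fuse",
    "stack_features",
    "late_fuse_train",
    "predict",
]

logger = logging.getLogger(__name__)

N_IMU_FEATURES = 84  # left + right wrist blocks


def default_imu_classifier(random_state: Optional[int] = None) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=100, random_state=random_state)


def default_vision_classifier(random_state: Optional[int] = None) -> LogisticRegression:
    # L2-regularised logistic model; C is the inverse regularisation strength
    return LogisticRegression(C=1.0, max_iter=1000, random_state=random_state)


def default_meta_classifier(random_state: Optional[int] = None) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=100, random_state=random_state)


def _split_blocks(X: np.ndarray, n_imu: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if X.shape[1] <= n_imu:
        raise ValueError(
            f"X has {X.shape[1]} columns; expected > {n_imu} "
            f"(imu block of {n_imu} followed by a non-empty vision block)")
    return X[:, :n_imu], X[:, n_imu:]


class EarlyFusionClassifier(ClassifierMixin, BaseEstimator):
    """Single model on the concatenated [imu_left | imu_right | vision] row.

    Parameters
    ----------
    estimator : classifier, optional
        Fitted on the full concatenated matrix; defaults to a 100-tree random
        forest.
    random_state : int, optional
        Seed for the default estimator.
    """

    def __init__(self, estimator=None, random_state: Optional[int] = None):
        self.estimator = estimator
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        base = self.estimator if self.estimator is not None else \
            default_imu_classifier(self.random_state)
        self.estimator_ = clone(base).fit(X, y)
        self.classes_ = self.estimator_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self.estimator_.predict(np.asarray(X, dtype=np.float64))

    def predict_proba(self, X):
        check_is_fitted(self)
        return self.estimator_.predict_proba(np.asarray(X, dtype=np.float64))


class LateFusionClassifier(ClassifierMixin, BaseEstimator):
    """Probability-stacking fusion of an inertial and a vision block.

    Base classifiers are fitted per modality; their per-class probabilities are
    appended to the respective feature blocks and a meta classifier is trained
    on the concatenation. ``prob_mode`` controls how training-time
    probabilities are obtained: ``"in_sample"`` uses the fitted base models'
    probabilities on the training data itself, ``"out_of_fold"`` uses internal
    5-fold cross-validated probabilities to curb stacking leakage.

    Parameters
    ----------
    imu_estimator, vision_estimator, meta_estimator : classifiers, optional
        Defaults: random forest (imu), L2 logistic regression C=1 (vision),
        random forest (meta).
    n_imu_features : int
        Column count of the inertial block at the front of ``X`` (84 for two
        42-feature wrists).
    prob_mode : {"in_sample", "out_of_fold"}
    inner_folds : int
        Folds for out_of_fold probability generation.
    random_state : int, optional

    Attributes
    ----------
    imu_estimator_, vision_estimator_, meta_estimator_ : fitted models
    classes_ : ndarray of class labels
    """

    def __init__(
        self,
        imu_estimator=None,
        vision_estimator=None,
        meta_estimator=None,
        n_imu_features: int = N_IMU_FEATURES,
        prob_mode: str = "in_sample",
        inner_folds: int = 5,
        random_state: Optional[int] = None,
    ):
        self.imu_estimator = imu_estimator
        self.vision_estimator = vision_estimator
        self.meta_estimator = meta_estimator
        self.n_imu_features = n_imu_features
        self.prob_mode = prob_mode
        self.inner_folds = inner_folds
        self.random_state = random_state

    def _bases(self):
        imu = self.imu_estimator if self.imu_estimator is not None else \
            default_imu_classifier(self.random_state)
        vis = self.vision_estimator if self.vision_estimator is not None else \
            default_vision_classifier(self.random_state)
        meta = self.meta_estimator if self.meta_estimator is not None else \
            default_meta_classifier(self.random_state)
        return clone(imu), clone(vis), clone(meta)

    def fit(self, X, y):
        if self.prob_mode not in ("in_sample", "out_of_fold"):
            raise ValueError("prob_mode must be 'in_sample' or 'out_of_fold'")
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError(
                f"training data must contain >= 2 classes, got {np.unique(y)!r}")
        X_imu, X_vis = _split_blocks(X, self.n_imu_features)
        imu, vis, meta = self._bases()
        self.imu_estimator_ = imu.fit(X_imu, y)
        self.vision_estimator_ = vis.fit(X_vis, y)
        if self.prob_mode == "in_sample":
            p_imu = self.imu_estimator_.predict_proba(X_imu)
            p_vis = self.vision_estimator_.predict_proba(X_vis)
        else:
            counts = np.unique(y, return_counts=True)[1]
            folds = int(min(self.inner_folds, counts.min()))
            if folds < 2:
                raise ValueError("out_of_fold stacking needs >= 2 samples per class")
            cv = StratifiedKFold(folds, shuffle=True, random_state=self.random_state)
            p_imu = cross_val_predict(clone(imu), X_imu, y, cv=cv,
                                      method="predict_proba")
            p_vis = cross_val_predict(clone(vis), X_vis, y, cv=cv,
                                      method="predict_proba")
        meta_X = np.hstack([X_imu, p_imu, X_vis, p_vis])
        self.meta_estimator_ = meta.fit(meta_X, y)
        self.classes_ = self.meta_estimator_.classes_
        self.n_features_in_ = X.shape[1]
        self.meta_input_dim_ = meta_X.shape[1]
        return self

    def _meta_features(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns; model expects {self.n_features_in_} "
                f"([imu {self.n_imu_features} | vision "
                f"{self.n_features_in_ - self.n_imu_features}])")
        X_imu, X_vis = _split_blocks(X, self.n_imu_features)
        p_imu = self.imu_estimator_.predict_proba(X_imu)
        p_vis = self.vision_estimator_.predict_proba(X_vis)
        return np.hstack([X_imu, p_imu, X_vis, p_vis])

    def predict(self, X):
        check_is_fitted(self)
        if np.asarray(X).shape[0] == 0:
            return np.empty(0, dtype=self.classes_.dtype)
        return self.meta_estimator_.predict(self._meta_features(X))

    def predict_proba(self, X):
        check_is_fitted(self)
        if np.asarray(X).shape[0] == 0:
            return np.empty((0, len(self.classes_)))
        return self.meta_estimator_.predict_proba(self._meta_features(X))


# ---------------------------------------------------------------------------
# Thin functional wrappers over the estimators


def early_fuse(instances: Sequence[FusedInstance],
               n_imu: int = N_IMU_FEATURES,
               n_vision: Optional[int] = None) -> tuple[np.ndarray, list[FusedInstance]]:
    """Stack instances into an early-fusion matrix [imu_left|imu_right|vision].

    Instances missing a block are dropped (and logged). Returns the matrix and
    the retained instances in input order.
    """
    rows, kept, dropped = [], [], 0
    for inst in instances:
        if inst.imu_features is None or inst.vision_features is None:
            dropped += 1
            continue
        rows.append(np.concatenate([inst.imu_features, inst.vision_features]))
        kept.append(inst)
    if dropped:
        logger.info("early_fuse dropped %d instances missing a block", dropped)
    if not rows:
        width = n_imu + (n_vision if n_vision is not None else 0)
        return np.empty((0, width)), []
    return np.vstack(rows), kept


def stack_features(instances: Sequence[FusedInstance]) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) for instances carrying both blocks, X = [imu | vision]."""
    X, kept = early_fuse(instances)
    y = np.array([inst.label for inst in kept])
    return X, y


def late_fuse_train(
    train: Sequence[FusedInstance],
    base_imu=None,
    base_vis=None,
    meta=None,
    prob_mode: str = "in_sample",
    random_state: Optional[int] = None,
) -> LateFusionClassifier:
    """Fit a late-fusion model on fused instances (see LateFusionClassifier)."""
    if not train:
        raise ValueError("empty training set")
    X, y = stack_features(train)
    n_imu = len(train[0].imu_features)
    model = LateFusionClassifier(
        imu_estimator=base_imu, vision_estimator=base_vis, meta_estimator=meta,
        n_imu_features=n_imu, prob_mode=prob_mode, random_state=random_state,
    )
    return model.fit(X, y)


def predict(model, instances: Sequence[FusedInstance]
            ) -> tuple[np.ndarray, np.ndarray]:
    """Labels and per-class probabilities for fused instances."""
    if not instances:
        return np.empty(0, dtype=object), np.empty((0, 0))
    X, kept = early_fuse(instances)
    if len(kept) != len(instances):
        raise ValueError("instances missing feature blocks cannot be predicted")
    return model.predict(X), model.predict_proba(X)
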