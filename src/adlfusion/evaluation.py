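"""Window labeling, verb reduction, de-overlap subsampling and the three
evaluation protocols (repeated k-fold CV, fixed cross-subject split, and an
80/20 split with grid search), all reporting per-class and macro
precision/recall/F1.

Overlapping sliding windows share raw samples, so train/test splits over the
raw window set would leak. Before any protocol runs, the window set is
subsampled to pairwise-disjoint windows: every other window for the 50%-overlap
vision/fused grids, every fourth for the 75%-overlap inertial grid.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, StratifiedKFold, KFold

from .types import AnnotationTrack, EvaluationReport, FusedInstance, TemporalWindow

__all__ = [
    "NONE_CLASS",
    "label_window",
    "reduce_label_to_verb",
    "deoverlap_subsample",
    "score",
    "repeated_cv",
    "fixed_split_eval",
    "grid_search",
]

logger = logging.getLogger(__name__)

NONE_CLASS = "none"
DEFAULT_MIN_COVER = 0.5


def label_window(
    window: TemporalWindow,
    track: AnnotationTrack,
    min_cover: float = DEFAULT_MIN_COVER,
) -> str:
    """Class of the interval with the largest temporal intersection.

    The winning intersection must cover at least ``min_cover`` of the window's
    length, else the background class ``"none"`` is returned. Ties go to the
    earlier-starting interval.
    """
    best_class = NONE_CLASS
    best_cover = 0
    for start, end, cls in track.intervals:  # sorted by start
        cover = window.intersection_ms(start, end)
        if cover > best_cover:
            best_cover = cover
            best_class = cls
    if best_cover < min_cover * window.length_ms:
        return NONE_CLASS
    return best_class


def reduce_label_to_verb(label: str) -> str:
    """First token of a compound ``verb-object1-preposition-object2`` label.

    Underscores bind within a token (``open-brownie_box`` -> ``open``); a label
    with no delimiter is returned unchanged.
    """
    if not label:
        raise ValueError("empty activity label")
    return label.split("-")[0].split()[0]


def deoverlap_subsample(
    instances: Sequence[FusedInstance], modality_mode: str
) -> list[FusedInstance]:
    """Keep only pairwise temporally-disjoint windows.

    ``vision_or_fused``: the vision grid overlaps 50%, so every other window
    (even grid index) is kept. ``imu_only``: the inertial grid overlaps 75%,
    so every fourth window (index divisible by 4) is kept.
    """
    if modality_mode == "vision_or_fused":
        step = 2
    elif modality_mode == "imu_only":
        step = 4
    else:
        raise ValueError("modality_mode must be 'vision_or_fused' or 'imu_only'")
    return [inst for inst in instances if inst.window.index % step == 0]


def score(
    predictions: Sequence[str],
    truths: Sequence[str],
    class_set: Sequence[str],
    scheme: str = "score",
    seed: Optional[int] = None,
) -> EvaluationReport:
    """Per-class one-vs-rest precision/recall/F1 plus unweighted macro averages.

    Classes with no predicted positives get precision 0 (and hence F1 0 when
    recall is also 0). Unknown labels raise.
    """
    predictions = list(predictions)
    truths = list(truths)
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    known = set(class_set)
    for lab in list(predictions) + list(truths):
        if lab not in known:
            raise ValueError(f"unknown label {lab!r}; class set is {sorted(known)}")
    labels = list(class_set)
    p, r, f, _ = precision_recall_fscore_support(
        truths, predictions, labels=labels, zero_division=0, average=None
    )
    per_class = {
        c: {"precision": float(pi), "recall": float(ri), "f1": float(fi)}
        for c, pi, ri, fi in zip(labels, p, r, f)
    }
    return EvaluationReport(
        per_class=per_class,
        macro_precision=float(np.mean(p)),
        macro_recall=float(np.mean(r)),
        macro_f1=float(np.mean(f)),
        scheme=scheme,
        seed=seed,
    )


def _mean_reports(reports: list[EvaluationReport], scheme: str,
                  repeats: int, seed: Optional[int]) -> EvaluationReport:
    classes = list(reports[0].per_class)
    per_class = {
        c: {
            m: float(np.mean([rep.per_class[c][m] for rep in reports]))
            for m in ("precision", "recall", "f1")
        }
        for c in classes
    }
    return EvaluationReport(
        per_class=per_class,
        macro_precision=float(np.mean([r.macro_precision for r in reports])),
        macro_recall=float(np.mean([r.macro_recall for r in reports])),
        macro_f1=float(np.mean([r.macro_f1 for r in reports])),
        scheme=scheme,
        repeats=repeats,
        seed=seed,
    )


def repeated_cv(
    X: np.ndarray,
    y: Sequence[str],
    estimator,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    stratified: bool = True,
    class_set: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Repeated k-fold cross-validation with fresh fold draws per repeat.

    For each repeat a new k-fold partition is drawn from ``seed + repeat``;
    per-class metrics are computed on the pooled out-of-fold predictions of
    that repeat and averaged across repeats. When some class has fewer than
    ``k`` members, k is lowered to the smallest class count (with a warning).
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs at least two classes")
    k_eff = int(min(k, counts.min())) if stratified else k
    if k_eff < k:
        logger.warning("lowering folds from %d to %d (smallest class has %d)",
                       k, k_eff, counts.min())
    if k_eff < 2:
        raise ValueError("not enough instances per class for 2 folds")
    labels = list(class_set) if class_set is not None else [str(c) for c in classes]
    reports = []
    for rep in range(repeats):
        splitter = (StratifiedKFold if stratified else KFold)(
            n_splits=k_eff, shuffle=True, random_state=seed + rep)
        pooled_pred = np.empty(len(y), dtype=object)
        for train_idx, test_idx in splitter.split(X, y):
            model = clone(estimator).fit(X[train_idx], y[train_idx])
            pooled_pred[test_idx] = model.predict(X[test_idx])
        reports.append(score(list(pooled_pred), list(y), labels))
    return _mean_reports(reports, f"{k_eff}-fold-cv", repeats, seed)


def _oversample_balanced(idx_by_class: dict[str, np.ndarray], rng: np.random.Generator
                         ) -> np.ndarray:
    """Indices after random oversampling of each class to the majority count."""
    target = max(len(v) for v in idx_by_class.values())
    chosen = []
    for cls in sorted(idx_by_class):
        idx = idx_by_class[cls]
        chosen.append(idx)
        deficit = target - len(idx)
        if deficit > 0:
            chosen.append(rng.choice(idx, size=deficit, replace=True))
    return np.concatenate(chosen)


def fixed_split_eval(
    X: np.ndarray,
    y: Sequence[str],
    subjects: Sequence[str],
    estimator,
    train_subjects: Sequence[str],
    test_subjects: Sequence[str],
    resample_balanced: bool = False,
    seed: int = 0,
    class_set: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Cross-subject evaluation on a fixed subject split.

    Trains on all instances of ``train_subjects`` (optionally with random
    oversampling of minority classes to the majority count — training set
    only) and evaluates on ``test_subjects``. The subject sets must be
    disjoint, which rules out any window-level leakage across the split.
    """
    train_set, test_set = set(train_subjects), set(test_subjects)
    if train_set & test_set:
        raise ValueError(f"overlapping subject sets: {sorted(train_set & test_set)}")
    X = np.asarray(X)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    train_mask = np.isin(subjects, list(train_set))
    test_mask = np.isin(subjects, list(test_set))
    train_idx = np.flatnonzero(train_mask)
    test_idx = np.flatnonzero(test_mask)
    if train_idx.size == 0 or test_idx.size == 0:
        raise ValueError("empty train or test subject partition")
    if resample_balanced:
        rng = np.random.default_rng(seed)
        by_class = {str(c): train_idx[y[train_idx] == c]
                    for c in np.unique(y[train_idx])}
        train_idx = _oversample_balanced(by_class, rng)
    model = clone(estimator).fit(X[train_idx], y[train_idx])
    preds = model.predict(X[test_idx])
    labels = list(class_set) if class_set is not None else \
        sorted({str(c) for c in np.unique(y)})
    rep = score(list(preds), list(y[test_idx]), labels,
                scheme="fixed-subject-split", seed=seed)
    return rep


def grid_search(
    X: np.ndarray,
    y: Sequence[str],
    estimator,
    param_grid: dict | list[dict],
    train_fraction: float = 0.8,
    inner_k: int = 5,
    seed: int = 0,
    class_set: Optional[Sequence[str]] = None,
) -> tuple[dict, EvaluationReport]:
    """80/20 split + grid search with inner k-fold CV on the training part.

    Parameters maximising mean inner-CV macro F1 are selected (ties resolved
    to the first point in grid order), the model is refitted on the full
    training split, and test-split metrics are reported.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_train = int(round(train_fraction * len(y)))
    train_idx, test_idx = order[:n_train], order[n_train:]
    if train_idx.size == 0 or test_idx.size == 0:
        raise ValueError("degenerate train/test split")
    counts = np.unique(y[train_idx], return_counts=True)[1]
    k_eff = int(min(inner_k, counts.min()))
    if k_eff < 2:
        raise ValueError("not enough training instances per class for grid search")
    cv = StratifiedKFold(k_eff, shuffle=True, random_state=seed)
    gs = GridSearchCV(clone(estimator), param_grid, scoring="f1_macro", cv=cv,
                      refit=True)
    gs.fit(X[train_idx], y[train_idx])
    preds = gs.best_estimator_.predict(X[test_idx])
    labels = list(class_set) if class_set is not None else \
        sorted({str(c) for c in np.unique(y)})
    report = score(list(preds), list(y[test_idx]), labels,
                   scheme="gridsearch-80-20", seed=seed)
    return dict(gs.best_params_), report
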