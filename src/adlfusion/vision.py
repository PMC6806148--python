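"""Hand-object interaction features from per-frame detection records.

Each frame that contains a hand detection yields a vector with one entry per
catalog class (the hand class excluded): the fraction of that object's box
covered by the hand box, maximised over instances. Frames without a hand get a
sentinel vector of -1. Frame vectors are then averaged over fixed-size frame
windows (default: 10 frames, stride 5) to produce the windowed vision features
that are matched against the inertial windows.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .types import BoundingBox, FrameDetections, Modality, TemporalWindow

__all__ = [
    "select_hand",
    "overlap",
    "frame_feature",
    "window_vision_features",
    "catalog_feature_names",
]

logger = logging.getLogger(__name__)

DEFAULT_HAND_CLASS = "person"
DEFAULT_MIN_CONF = 0.5
DEFAULT_WINDOW_SIZE = 10
DEFAULT_STRIDE = 5
DEFAULT_FRAME_PERIOD_MS = 40  # 25 fps


def catalog_feature_names(catalog: Sequence[str], hand_class: str = DEFAULT_HAND_CLASS
                          ) -> list[str]:
    """Feature positions in catalog order, hand class removed."""
    if hand_class not in catalog:
        raise ValueError(f"hand class {hand_class!r} not in catalog")
    return [c for c in catalog if c != hand_class]


def select_hand(
    frame: FrameDetections,
    hand_class: str = DEFAULT_HAND_CLASS,
    min_conf: float = DEFAULT_MIN_CONF,
) -> Optional[BoundingBox]:
    """Highest-confidence hand box above the confidence threshold.

    Ties broken by larger area, then lowest x_min; ``None`` if no hand
    detection qualifies.
    """
    candidates = [
        b for b in frame.boxes
        if b.class_label == hand_class and b.confidence >= min_conf
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda b: (b.confidence, b.area, -b.x_min))


def overlap(hand: BoundingBox, obj: BoundingBox) -> float:
    """Fraction of the object's box covered by the hand box.

    ``area(hand ∩ obj) / area(obj)`` with half-open pixel intervals; 0 when
    disjoint, 1 when the hand fully covers the object. Normalising by the
    object (not the union) means a hand engulfing a small object scores 1,
    which is the interaction reading intended here.
    """
    obj_area = obj.area
    if obj_area <= 0:
        logger.warning("degenerate zero-area object box %s", obj)
        return 0.0
    iw = min(hand.x_max, obj.x_max) - max(hand.x_min, obj.x_min)
    ih = min(hand.y_max, obj.y_max) - max(hand.y_min, obj.y_min)
    if iw <= 0 or ih <= 0:
        return 0.0
    return float(iw * ih / obj_area)


def overlap_iou(hand: BoundingBox, obj: BoundingBox) -> float:
    """Intersection-over-union alternative normalisation (config option)."""
    iw = min(hand.x_max, obj.x_max) - max(hand.x_min, obj.x_min)
    ih = min(hand.y_max, obj.y_max) - max(hand.y_min, obj.y_min)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = hand.area + obj.area - inter
    return float(inter / union) if union > 0 else 0.0


def frame_feature(
    frame: FrameDetections,
    catalog: Sequence[str],
    hand_class: str = DEFAULT_HAND_CLASS,
    min_conf: float = DEFAULT_MIN_CONF,
    overlap_fn=overlap,
) -> np.ndarray:
    """Single-frame interaction vector over the catalog (hand class excluded).

    All -1 when no hand is detected; otherwise, per object class, the maximum
    overlap with the hand over that class's instances (0 if the class is
    absent from the frame).
    """
    classes = catalog_feature_names(catalog, hand_class)
    hand = select_hand(frame, hand_class, min_conf)
    if hand is None:
        return np.full(len(classes), -1.0)
    values = np.zeros(len(classes))
    index = {c: i for i, c in enumerate(classes)}
    for box in frame.boxes:
        if box.class_label == hand_class or box.confidence < min_conf:
            continue
        i = index.get(box.class_label)
        if i is None:
            continue
        values[i] = max(values[i], overlap_fn(hand, box))
    return values


def window_vision_features(
    frames: Sequence[FrameDetections],
    catalog: Sequence[str],
    window_size: int = DEFAULT_WINDOW_SIZE,
    stride: int = DEFAULT_STRIDE,
    frame_period_ms: int = DEFAULT_FRAME_PERIOD_MS,
    hand_class: str = DEFAULT_HAND_CLASS,
    min_conf: float = DEFAULT_MIN_CONF,
    sentinel_mode: str = "include",
    overlap_fn=overlap,
) -> tuple[np.ndarray, list[TemporalWindow]]:
    """Windowed vision features: mean of consecutive single-frame vectors.

    Windows cover ``window_size`` consecutive frames advanced by ``stride``
    frames; trailing partial windows are dropped. A window's timespan runs
    from its first frame's timestamp to its last frame's timestamp plus one
    frame period (half-open).

    ``sentinel_mode`` controls hand-less frames: ``"include"`` averages their
    -1 vectors in; ``"exclude"`` averages only hand frames (a window with no
    hand frame at all stays all -1).
    """
    if window_size < 1 or stride < 1:
        raise ValueError("window_size and stride must be >= 1")
    if sentinel_mode not in ("include", "exclude"):
        raise ValueError("sentinel_mode must be 'include' or 'exclude'")
    n_classes = len(catalog_feature_names(catalog, hand_class))
    if len(frames) < window_size:
        return np.empty((0, n_classes)), []
    per_frame = np.array([
        frame_feature(f, catalog, hand_class, min_conf, overlap_fn) for f in frames
    ])
    rows = []
    windows = []
    k = 0
    for start in range(0, len(frames) - window_size + 1, stride):
        block = per_frame[start:start + window_size]
        if sentinel_mode == "include":
            vec = block.mean(axis=0)
        else:
            hand_rows = block[~np.all(block == -1.0, axis=1)]
            vec = hand_rows.mean(axis=0) if hand_rows.size else np.full(n_classes, -1.0)
        rows.append(vec)
        windows.append(TemporalWindow(
            int(frames[start].frame_t),
            int(frames[start + window_size - 1].frame_t) + int(frame_period_ms),
            index=k,
            modality=Modality.VISION,
        ))
        k += 1
    return np.vstack(rows), windows
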