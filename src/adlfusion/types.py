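"""Core domain types shared across the pipeline.

All timestamps are integer milliseconds on a single "unified" timeline, and
every interval and window is half-open ``[start_ms, end_ms)`` — one convention
at every boundary in the codebase.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "WristPosition",
    "Modality",
    "InertialStream",
    "TemporalWindow",
    "BoundingBox",
    "FrameDetections",
    "AnnotationTrack",
    "AlignmentOffsets",
    "FusedInstance",
    "EvaluationReport",
]


class WristPosition(str, enum.Enum):
    LEFT_WRIST = "left_wrist"
    RIGHT_WRIST = "right_wrist"


class Modality(str, enum.Enum):
    IMU = "imu"
    VISION = "vision"


@dataclass
class InertialStream:
    """A timestamped 3-axis acceleration series from one wrist device.

    Parameters
    ----------
    device_id : str
        Free-text device identifier.
    position : WristPosition
        Which wrist the device was worn on.
    t : ndarray of int64, shape (n,)
        Sample timestamps in milliseconds, strictly increasing.
    a : ndarray of float64, shape (n, 3)
        Acceleration samples (x, y, z) in m/s².
    nominal_rate_hz : float
        Nominal sampling rate; 50 Hz for the wrist devices emulated here.
    """

    device_id: str
    position: WristPosition
    t: np.ndarray
    a: np.ndarray
    nominal_rate_hz: float = 50.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.a = np.asarray(self.a, dtype=np.float64)
        if self.a.ndim != 2 or self.a.shape[1] != 3:
            raise ValueError(f"acceleration must be (n, 3), got {self.a.shape}")
        if self.t.shape[0] != self.a.shape[0]:
            raise ValueError("timestamp and acceleration lengths differ")
        if not np.all(np.isfinite(self.a)):
            raise ValueError("non-finite acceleration values")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if np.any(dt == 0):
                raise ValueError("duplicate timestamps in stream")
            if np.any(dt < 0):
                raise ValueError("timestamps not strictly increasing")
        if self.nominal_rate_hz <= 0:
            raise ValueError("nominal_rate_hz must be positive")
        self.position = WristPosition(self.position)

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def span(self) -> tuple[int, int]:
        """(first_t, last_t + one nominal sample period) — half-open coverage."""
        if len(self) == 0:
            raise ValueError("empty stream has no span")
        period = int(round(1000.0 / self.nominal_rate_hz))
        return int(self.t[0]), int(self.t[-1]) + period

    def shifted(self, offset_ms: int) -> "InertialStream":
        """Return a copy with ``offset_ms`` added to every timestamp."""
        return InertialStream(
            self.device_id, self.position, self.t + int(offset_ms),
            self.a.copy(), self.nominal_rate_hz,
        )


@dataclass(frozen=True)
class TemporalWindow:
    """Half-open [start_ms, end_ms) span on the unified timeline."""

    start_ms: int
    end_ms: int
    index: int
    modality: Modality

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("window end must exceed start")

    @property
    def length_ms(self) -> int:
        return self.end_ms - self.start_ms

    def intersection_ms(self, start: int, end: int) -> int:
        """Length of overlap with another half-open interval, in ms."""
        return max(0, min(self.end_ms, end) - max(self.start_ms, start))


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, origin top-left, half-open pixel intervals."""

    class_label: str
    confidence: float
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        # normalize numpy scalars to plain floats so serialization is uniform
        for name in ("confidence", "x_min", "y_min", "x_max", "y_max"):
            object.__setattr__(self, name, float(getattr(self, name)))
        coords = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(np.isfinite(c) for c in coords):
            raise ValueError("non-finite box coordinates")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("box coordinates must be ordered (min < max)")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass
class FrameDetections:
    """One video frame's set of class-labeled boxes."""

    frame_t: int
    frame_index: int
    boxes: list[BoundingBox] = field(default_factory=list)


@dataclass
class AnnotationTrack:
    """Labeled activity intervals (start_ms, end_ms, class) for one session.

    Intervals must be non-overlapping within the track.
    """

    intervals: list[tuple[int, int, str]]
    subject: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        for s, e, c in self.intervals:
            if e <= s:
                raise ValueError(f"interval ({s}, {e}, {c!r}) has end <= start")
        ordered = sorted(self.intervals, key=lambda iv: iv[0])
        for (s1, e1, c1), (s2, e2, c2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping intervals ({s1},{e1},{c1!r}) and ({s2},{e2},{c2!r})"
                )
        self.intervals = ordered

    @property
    def classes(self) -> list[str]:
        return sorted({c for _, _, c in self.intervals})


@dataclass
class AlignmentOffsets:
    """Per-source signed offsets (ms) that map native timestamps onto the
    unified timeline: unified_t = native_t + offset_ms[source]."""

    offsets_ms: dict[str, int]
    reference_source: str

    def __post_init__(self) -> None:
        if self.reference_source not in self.offsets_ms:
            raise ValueError("reference source missing from offsets")
        if self.offsets_ms[self.reference_source] != 0:
            raise ValueError("reference source offset must be 0")


@dataclass
class FusedInstance:
    """One aligned window with its feature blocks and label."""

    subject: str
    session: str
    window: TemporalWindow
    label: str
    imu_features: Optional[np.ndarray] = None
    vision_features: Optional[np.ndarray] = None
    imu_probs: Optional[np.ndarray] = None
    vision_probs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.imu_features is None and self.vision_features is None:
            raise ValueError("at least one feature block must be present")
        for probs in (self.imu_probs, self.vision_probs):
            if probs is not None and abs(float(np.sum(probs)) - 1.0) > 1e-9:
                raise ValueError("probability vector does not sum to 1")


@dataclass
class EvaluationReport:
    """Per-class and macro precision/recall/F1 for one evaluation protocol."""

    per_class: dict[str, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    scheme: str
    repeats: int = 1
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "repeats": self.repeats,
            "seed": self.seed,
            "per_class": self.per_class,
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
        }

    def to_frame(self):
        """Per-class rows plus a macro row, columns precision/recall/f1."""
        import pandas as pd

        rows = {c: m for c, m in self.per_class.items()}
        rows["macro"] = {
            "precision": self.macro_precision,
            "recall": self.macro_recall,
            "f1": self.macro_f1,
        }
        return pd.DataFrame.from_dict(rows, orient="index")[
            ["precision", "recall", "f1"]
        ]
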