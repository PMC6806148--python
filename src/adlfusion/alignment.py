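"""Temporal alignment of the modalities onto one unified timeline.

Recordings start with a deliberate stillness period; the first movement is
detectable in every source, and the differences between per-source motion-start
timestamps give the clock offsets. After shifting, all sources are trimmed to
their common span (latest start, earliest end), and vision windows are matched
to inertial windows by the earliest inertial window starting at or after the
vision window's start.
"""
from __future__ import annotations

import bisect
from typing import Optional, Sequence

import numpy as np

from .types import AlignmentOffsets, InertialStream, TemporalWindow

__all__ = [
    "detect_motion_start",
    "detect_vision_activity_start",
    "compute_offsets",
    "trim_to_common_span",
    "match_windows",
    "match_all",
]


class AlignmentError(RuntimeError):
    pass


def _consecutive_runs(flags: np.ndarray, consecutive: int) -> np.ndarray:
    """Indices where ``consecutive`` flags in a row are all set."""
    if consecutive <= 1:
        return np.flatnonzero(flags)
    n_runs = len(flags) - consecutive + 1
    if n_runs <= 0:
        return np.empty(0, dtype=np.intp)
    runs = np.ones(n_runs, dtype=bool)
    for k in range(consecutive):
        runs &= flags[k:k + n_runs]
    return np.flatnonzero(runs)


def detect_motion_start(
    stream: InertialStream,
    still_threshold: float = 0.5,
    min_still_ms: int = 1000,
    consecutive: int = 3,
) -> int:
    """First timestamp at which the stream leaves its stillness baseline.

    The baseline is the per-axis median acceleration over the first
    ``min_still_ms`` (the gravity vector during stillness). Motion starts at
    the first sample where the acceleration vector deviates from the baseline
    by more than ``still_threshold`` (m/s², Euclidean norm) for
    ``consecutive`` samples in a row, searching after the baseline period.
    The full-vector deviation also catches motion orthogonal to gravity,
    which a magnitude-only criterion misses.

    Raises :class:`AlignmentError` if the stream has no adequate stillness
    prefix or never moves — supply manual offsets in that case.
    """
    if len(stream) < consecutive + 1:
        raise AlignmentError("stream too short for motion detection")
    prefix_end = int(np.searchsorted(stream.t, stream.t[0] + min_still_ms, side="left"))
    if prefix_end < 2:
        raise AlignmentError(
            "no stillness prefix found; provide manual offsets")
    if still_threshold <= 0:
        # degenerate threshold: everything after the mandatory stillness counts
        return int(stream.t[prefix_end])
    baseline = np.median(stream.a[:prefix_end], axis=0)
    dev = np.linalg.norm(stream.a - baseline, axis=1) > still_threshold
    if _consecutive_runs(dev[:prefix_end], consecutive).size:
        raise AlignmentError(
            "stillness prefix itself contains motion; provide manual offsets")
    hits = _consecutive_runs(dev[prefix_end:], consecutive)
    if hits.size == 0:
        raise AlignmentError(
            "no motion found after stillness prefix; provide manual offsets")
    return int(stream.t[prefix_end + int(hits[0])])


def detect_vision_activity_start(frames, hand_class: str = "person",
                                 consecutive: int = 3) -> int:
    """First frame timestamp of a run of frames containing non-hand objects.

    The stillness lead-in shows no manipulated objects, so the first sustained
    object detection marks the activity onset in the vision clock — the
    counterpart of :func:`detect_motion_start` for the detection stream.
    """
    flags = np.array([
        any(b.class_label != hand_class for b in f.boxes) for f in frames
    ])
    hits = _consecutive_runs(flags, consecutive)
    if hits.size == 0:
        raise AlignmentError(
            "no object detections found; provide manual offsets")
    return int(frames[int(hits[0])].frame_t)


def compute_offsets(
    motion_starts: dict[str, int], reference_source: str
) -> AlignmentOffsets:
    """Offsets from per-source motion-start timestamps in native clocks.

    The physical motion start is simultaneous across sources, so the offset of
    source *s* is ``start(reference) - start(s)``: adding it to *s*'s native
    timestamps lands them on the reference timeline.
    """
    if reference_source not in motion_starts:
        raise ValueError(f"reference source {reference_source!r} missing")
    ref = motion_starts[reference_source]
    return AlignmentOffsets(
        {src: int(ref - t) for src, t in motion_starts.items()},
        reference_source,
    )


def trim_to_common_span(spans: dict[str, tuple[int, int]]) -> tuple[int, int]:
    """(latest start, earliest end) across all sources.

    Data outside this common span is discarded before feature extraction.
    """
    if not spans:
        raise ValueError("no spans given")
    start = max(s for s, _ in spans.values())
    end = min(e for _, e in spans.values())
    if start >= end:
        raise AlignmentError(
            f"no temporal overlap among sources (common span [{start}, {end}))")
    return start, end


def match_windows(
    vision_window: TemporalWindow, imu_grid: Sequence[TemporalWindow]
) -> Optional[TemporalWindow]:
    """The inertial window with the smallest start ts' satisfying ts' >= ts.

    ts is the vision window's start; ``None`` (window dropped) when every
    inertial window starts before ts.
    """
    starts = [w.start_ms for w in imu_grid]
    i = bisect.bisect_left(starts, vision_window.start_ms)
    if i >= len(imu_grid):
        return None
    return imu_grid[i]


def match_all(
    vision_windows: Sequence[TemporalWindow], imu_grid: Sequence[TemporalWindow]
) -> list[tuple[int, int]]:
    """Index pairs (vision_idx, imu_idx) for all matchable vision windows."""
    imu_pos = {id(w): i for i, w in enumerate(imu_grid)}
    pairs = []
    for vi, vw in enumerate(vision_windows):
        m = match_windows(vw, imu_grid)
        if m is not None:
            pairs.append((vi, imu_pos[id(m)]))
    return pairs
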