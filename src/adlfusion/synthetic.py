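"""Synthetic multimodal ADL sessions for testing the full pipeline.

Generates, per session: two 50 Hz wrist accelerometer streams, a 25 fps stream
of per-frame object detections, the ground-truth activity intervals, and the
true per-device clock offsets. Every stream starts with a stillness lead-in
(gravity plus noise only) before the first activity — the same convention the
alignment stage exploits to recover clock offsets.

The motion model is a per-class, per-wrist sum of sinusoids plus white noise:
enough to make the windowed time/frequency features class-discriminative while
staying fully controllable. The detection model draws a hand-object overlap
per frame from a per-class Beta law (or a degenerate constant) and realises it
geometrically, placing the object box against a fixed-size hand box so that
intersection-over-object-area equals the drawn value exactly; detector noise
(missed hands, false positives, box jitter) is applied on top. Frame images
are never generated — detection records are the pipeline's actual input
boundary.

Activity durations and gaps are quantised to the 200 ms vision-window stride so
annotation boundaries fall on window edges; partial windows then cover an
activity by exactly 0 %, 50 % or 100 %, which keeps window labels well defined.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np

from .types import (
    AlignmentOffsets,
    AnnotationTrack,
    BoundingBox,
    FrameDetections,
    InertialStream,
    WristPosition,
)

__all__ = [
    "Sinusoid",
    "MotionTemplate",
    "ScenarioConfig",
    "default_config",
    "make_confusable_design",
    "generate_session",
    "generate_cohort",
]

GRAVITY = np.array([0.0, 0.0, 9.81])

HAND_BOX = (800.0, 400.0, 1100.0, 700.0)  # fixed 300x300 hand in a 1920x1080 frame
OBJECT_SIZE = (120.0, 120.0)

#: Activity vocabulary of the emulated ADL scenario.
ADL_CLASSES = {
    "A1": "drink",
    "A2": "eat",
    "A3": "take_meds",
    "A4": "prepare_meal",
    "A5": "take_snack",
    "A6": "wipe_mouth",
}

# The two scripted activity sequences performed in alternation.
DEFAULT_SEQUENCES = (
    ("take_snack", "take_meds", "drink", "take_snack", "wipe_mouth"),
    ("prepare_meal", "eat", "take_meds", "drink", "eat", "wipe_mouth"),
)

#: Boundary quantum: durations/gaps snap to the vision window stride (5 frames
#: at 25 fps = 200 ms) so annotation edges coincide with window edges.
BOUNDARY_QUANTUM_MS = 200


@dataclass(frozen=True)
class Sinusoid:
    amplitude: float   # m/s²
    freq_hz: float
    phase: float = 0.0


@dataclass(frozen=True)
class MotionTemplate:
    """Per-wrist, per-axis sinusoid mixtures for one activity class."""

    left: tuple[tuple[Sinusoid, ...], ...]   # 3 axes
    right: tuple[tuple[Sinusoid, ...], ...]

    def signal(self, wrist: str, t_ms: np.ndarray, onset_ms: int = 0) -> np.ndarray:
        """Evaluate at times ``t_ms`` with phase referenced to ``onset_ms``.

        Cosine convention: each component is at full amplitude at the activity
        onset, so movement begins with an acceleration jump — the feature the
        stillness-based alignment relies on.
        """
        axes = self.left if wrist == "left" else self.right
        t = (t_ms - onset_ms) / 1000.0
        out = np.zeros((t.size, 3))
        for i, comps in enumerate(axes):
            for s in comps:
                out[:, i] += s.amplitude * np.cos(2 * np.pi * s.freq_hz * t + s.phase)
        return out


def _axes(*specs) -> tuple[tuple[Sinusoid, ...], ...]:
    return tuple(tuple(Sinusoid(*c) for c in axis) for axis in specs)


def _template(left_specs, right_specs) -> MotionTemplate:
    return MotionTemplate(_axes(*left_specs), _axes(*right_specs))


# Distinct frequency/amplitude signatures per class; the dominant wrist varies.
DEFAULT_TEMPLATES: dict[str, MotionTemplate] = {
    "drink": _template(
        ([(0.4, 0.9)], [(0.3, 1.1)], [(0.2, 0.7)]),
        ([(2.5, 1.2)], [(1.8, 0.8, 1.0)], [(1.2, 1.6)]),
    ),
    "eat": _template(
        ([(1.5, 2.0)], [(1.0, 1.4)], [(0.8, 2.4)]),
        ([(2.0, 2.2)], [(1.4, 1.8, 0.5)], [(1.0, 2.6)]),
    ),
    "take_meds": _template(
        ([(1.0, 3.0)], [(0.6, 2.2)], [(0.5, 3.4)]),
        ([(2.2, 3.2)], [(1.2, 2.6)], [(0.8, 3.8)]),
    ),
    "prepare_meal": _template(
        ([(2.8, 4.0)], [(2.0, 3.2)], [(1.5, 4.6)]),
        ([(2.8, 4.2, 0.7)], [(2.0, 3.4)], [(1.5, 4.8)]),
    ),
    "take_snack": _template(
        ([(0.8, 1.6)], [(0.5, 1.0)], [(0.4, 2.0)]),
        ([(1.8, 0.6)], [(1.2, 1.5)], [(0.9, 0.9, 0.3)]),
    ),
    "wipe_mouth": _template(
        ([(0.5, 5.0)], [(0.3, 4.0)], [(0.3, 5.6)]),
        ([(1.6, 5.2)], [(1.0, 4.4)], [(0.7, 6.0)]),
    ),
}

# Per class: object classes visible during the activity, with overlap laws.
# A value is either (alpha, beta) Beta parameters or a degenerate constant.
OverlapLaw = Union[tuple[float, float], float]

DEFAULT_OBJECT_MODELS: dict[str, dict[str, OverlapLaw]] = {
    "drink": {"cup": (5.0, 2.0)},
    "eat": {"plate": (4.0, 2.0), "fork": (3.0, 3.0)},
    "take_meds": {"pill_bottle": (6.0, 2.0), "cup": (2.0, 5.0)},
    "prepare_meal": {"knife": (3.0, 3.0), "bread": (4.0, 3.0)},
    "take_snack": {"snack_bag": (5.0, 3.0)},
    "wipe_mouth": {"napkin": (6.0, 2.0)},
}


@dataclass
class ScenarioConfig:
    """Full description of a synthetic recording campaign.

    Defaults emulate the study conditions: 2 subjects x 6 sessions, two
    scripted activity sequences performed in alternation, 50 Hz wrists,
    25 fps egocentric detections, a stillness lead-in, and short interruptions
    between activities.
    """

    seed: int
    subjects: int = 2
    sessions_per_subject: int = 6
    activity_sequences: tuple[tuple[str, ...], ...] = DEFAULT_SEQUENCES
    duration_range_ms: tuple[int, int] = (2000, 4000)
    gap_mode: str = "interrupted"            # "natural" | "interrupted"
    gap_range_ms: tuple[int, int] = (1000, 2000)
    imu_rate_hz: float = 50.0
    fps: float = 25.0
    stillness_lead_ms: int = 5200
    tail_ms: int = 2000
    offsets_ms: dict[str, int] = field(
        default_factory=lambda: {"vision": 0, "imu_left": 0, "imu_right": 0})
    reference_source: str = "vision"
    motion_templates: dict[str, MotionTemplate] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES))
    object_models: dict[str, dict[str, OverlapLaw]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OBJECT_MODELS.items()})
    hand_class: str = "person"
    distractor_classes: tuple[str, ...] = ("chair",)
    miss_prob: float = 0.05
    fp_rate: float = 0.02
    box_jitter_px: float = 2.0
    conf_range: tuple[float, float] = (0.6, 1.0)
    accel_noise_sd: float = 0.1   # resting MEMS accelerometer noise floor

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.subjects < 1 or self.sessions_per_subject < 1:
            raise ValueError("subjects and sessions_per_subject must be >= 1")
        if self.imu_rate_hz <= 0 or self.fps <= 0:
            raise ValueError("rates must be positive")
        if self.gap_mode not in ("natural", "interrupted"):
            raise ValueError("gap_mode must be 'natural' or 'interrupted'")
        if not (0 <= self.miss_prob <= 1 and 0 <= self.fp_rate <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.duration_range_ms[0] > self.duration_range_ms[1] or \
                self.duration_range_ms[0] <= 0:
            raise ValueError("invalid duration range")
        if self.accel_noise_sd < 0 or self.box_jitter_px < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.offsets_ms.get(self.reference_source, None) != 0:
            raise ValueError("reference source must have offset 0")
        for seq in self.activity_sequences:
            for cls in seq:
                if cls not in self.motion_templates:
                    raise ValueError(f"class {cls!r} has no motion template")
                if cls not in self.object_models:
                    raise ValueError(f"class {cls!r} has no object model")

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for seq in self.activity_sequences:
            for c in seq:
                if c not in seen:
                    seen.append(c)
        return seen

    @property
    def catalog(self) -> list[str]:
        objs = sorted({o for m in self.object_models.values() for o in m})
        extras = sorted(c for c in self.distractor_classes if c not in objs)
        return [self.hand_class] + objs + extras


def default_config(seed: int) -> ScenarioConfig:
    return ScenarioConfig(seed=seed)


def make_confusable_design(base: ScenarioConfig) -> ScenarioConfig:
    """A scenario where each single modality is provably ambiguous.

    The first two classes share an identical motion template but use disjoint
    object sets (inertial data cannot separate them, vision can); the third
    and fourth classes share an identical object model but move differently
    (vision cannot separate them, inertial data can).
    """
    classes = base.classes
    if len(classes) < 4:
        raise ValueError(f"need >= 4 activity classes, got {len(classes)}")
    c1, c2, c3, c4 = classes[:4]
    templates = dict(base.motion_templates)
    templates[c2] = templates[c1]                       # motion twins
    templates[c3] = _template(
        ([(2.0, 2.5)], [(1.2, 1.8)], [(0.8, 3.0)]),
        ([(2.4, 2.7)], [(1.5, 2.0)], [(1.0, 3.2)]))
    templates[c4] = _template(
        ([(2.0, 4.5)], [(1.2, 3.6)], [(0.8, 5.2)]),
        ([(2.4, 4.8)], [(1.5, 3.9)], [(1.0, 5.5)]))    # distinct spectrum
    shared_obj: dict[str, OverlapLaw] = {"object_c": (4.0, 2.0)}
    objects: dict[str, dict[str, OverlapLaw]] = {
        c1: {"object_a": (5.0, 2.0)},
        c2: {"object_b": (5.0, 2.0)},                   # disjoint from c1
        c3: dict(shared_obj),                           # object twins
        c4: dict(shared_obj),
    }
    return replace(
        base,
        activity_sequences=((c1, c2, c3, c4), (c4, c3, c2, c1)),
        motion_templates=templates,
        object_models=objects,
        duration_range_ms=(3000, 3000),
        gap_mode="interrupted",
        gap_range_ms=(1000, 1000),
        stillness_lead_ms=5200,
    )


def _session_rng(config: ScenarioConfig, subject_idx: int, session_idx: int
                 ) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed,
                               spawn_key=(subject_idx, session_idx)))


def _quantize(x: float, quantum: int = BOUNDARY_QUANTUM_MS) -> int:
    return max(quantum, int(round(x / quantum)) * quantum)


def _draw_overlap(law: OverlapLaw, rng: np.random.Generator) -> float:
    if isinstance(law, (int, float)):
        return float(law)
    a, b = law
    return float(rng.beta(a, b))


def _place_object(hand: tuple[float, float, float, float], v: float
                  ) -> tuple[float, float, float, float]:
    """Object box whose intersection-over-own-area with the hand box equals v."""
    hx_min, hy_min, hx_max, hy_max = hand
    w, h = OBJECT_SIZE
    x_min = hx_max - v * w
    y_min = (hy_min + hy_max) / 2.0 - h / 2.0
    return (x_min, y_min, x_min + w, y_min + h)


def generate_session(
    config: ScenarioConfig, subject_idx: int, session_idx: int
) -> tuple[InertialStream, InertialStream, list[FrameDetections],
           AnnotationTrack, AlignmentOffsets]:
    """One session: two native-clock wrist streams, native-clock frame
    detections, unified-timeline annotations, and the true offsets."""
    rng = _session_rng(config, subject_idx, session_idx)
    seq = config.activity_sequences[session_idx % len(config.activity_sequences)]

    # --- unified-timeline schedule -------------------------------------
    intervals: list[tuple[int, int, str]] = []
    t = int(config.stillness_lead_ms)
    for i, cls in enumerate(seq):
        dur = _quantize(rng.uniform(*config.duration_range_ms))
        intervals.append((t, t + dur, cls))
        t += dur
        if config.gap_mode == "interrupted" and i < len(seq) - 1:
            t += _quantize(rng.uniform(*config.gap_range_ms))
    total_ms = t + int(config.tail_ms)
    track = AnnotationTrack(intervals, subject=f"subject{subject_idx}",
                            session=f"session{session_idx}")

    # --- inertial streams ----------------------------------------------
    period = 1000.0 / config.imu_rate_hz
    t_imu = np.arange(0, total_ms, period).round().astype(np.int64)
    streams = {}
    for wrist, position in (("left", WristPosition.LEFT_WRIST),
                            ("right", WristPosition.RIGHT_WRIST)):
        a = np.tile(GRAVITY, (t_imu.size, 1))
        if config.accel_noise_sd > 0:
            a = a + rng.normal(0.0, config.accel_noise_sd, a.shape)
        for start, end, cls in intervals:
            mask = (t_imu >= start) & (t_imu < end)
            a[mask] += config.motion_templates[cls].signal(wrist, t_imu[mask], start)
        offset = int(config.offsets_ms.get(f"imu_{wrist}", 0))
        streams[wrist] = InertialStream(
            device_id=f"imu_{wrist}", position=position,
            t=t_imu - offset, a=a, nominal_rate_hz=config.imu_rate_hz)

    # --- frame detections ----------------------------------------------
    frame_period = 1000.0 / config.fps
    t_frames = np.arange(0, total_ms, frame_period).round().astype(np.int64)
    vision_offset = int(config.offsets_ms.get("vision", 0))
    catalog = config.catalog
    frames: list[FrameDetections] = []
    starts = np.array([iv[0] for iv in intervals])
    ends = np.array([iv[1] for iv in intervals])
    for fi, ft in enumerate(t_frames):
        boxes: list[BoundingBox] = []
        hit = np.flatnonzero((starts <= ft) & (ft < ends))
        active_cls = intervals[int(hit[0])][2] if hit.size else None
        hand_present = rng.random() >= config.miss_prob
        if hand_present:
            hand_coords = HAND_BOX
            if config.box_jitter_px > 0:
                dx, dy = rng.normal(0.0, config.box_jitter_px, 2)
                hand_coords = (HAND_BOX[0] + dx, HAND_BOX[1] + dy,
                               HAND_BOX[2] + dx, HAND_BOX[3] + dy)
            boxes.append(BoundingBox(config.hand_class,
                                     float(rng.uniform(*config.conf_range)),
                                     *hand_coords))
        if active_cls is not None:
            for obj, law in config.object_models[active_cls].items():
                v = _draw_overlap(law, rng)
                coords = _place_object(HAND_BOX, v)
                if config.box_jitter_px > 0:
                    dx, dy = rng.normal(0.0, config.box_jitter_px, 2)
                    coords = (coords[0] + dx, coords[1] + dy,
                              coords[2] + dx, coords[3] + dy)
                boxes.append(BoundingBox(obj,
                                         float(rng.uniform(*config.conf_range)),
                                         *coords))
        if config.fp_rate > 0 and rng.random() < config.fp_rate:
            cls = catalog[int(rng.integers(1, len(catalog)))]  # any non-hand class
            x = float(rng.uniform(0, 400))
            y = float(rng.uniform(0, 400))
            boxes.append(BoundingBox(cls, float(rng.uniform(*config.conf_range)),
                                     x, y, x + OBJECT_SIZE[0], y + OBJECT_SIZE[1]))
        frames.append(FrameDetections(int(ft - vision_offset), fi, boxes))

    offsets = AlignmentOffsets(dict(config.offsets_ms), config.reference_source)
    return streams["left"], streams["right"], frames, track, offsets


def generate_cohort(config: ScenarioConfig, out_dir: Union[str, Path],
                    force: bool = False) -> Path:
    """Write subjects x sessions worth of files plus a hashed manifest."""
    from . import io as adl_io

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is non-empty; pass force=True")
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "subjects": config.subjects,
                      "sessions_per_subject": config.sessions_per_subject,
                      "catalog": config.catalog, "files": {}}
    adl_io.write_catalog(out / "catalog.txt", config.catalog)
    for si in range(config.subjects):
        for se in range(config.sessions_per_subject):
            left, right, frames, track, offsets = generate_session(config, si, se)
            d = out / f"subject{si}" / f"session{se}"
            d.mkdir(parents=True, exist_ok=True)
            adl_io.write_sensor_csv(d / "imu_left.csv", left)
            adl_io.write_sensor_csv(d / "imu_right.csv", right)
            adl_io.write_detections_csv(d / "detections.csv", frames)
            adl_io.write_annotations_csv(d / "annotations.csv", track)
            adl_io.write_offsets_csv(d / "offsets.csv", offsets)
            for f in sorted(d.iterdir()):
                rel = str(f.relative_to(out))
                manifest["files"][rel] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
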