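"""Readers and writers for the on-disk dialects.

Formats:

* sensor CSV — header ``timestamp_ms,x,y,z``, one row per sample;
* detection records — either a flat CSV
  (``frame_index,timestamp_ms,class,confidence,x_min,y_min,x_max,y_max``)
  or a JSON dialect (list of per-frame records with a box list);
* annotation CSV — ``start_ms,end_ms,class,subject,session``;
* offsets CSV — ``source,offset_ms`` with the reference source (offset 0)
  listed first;
* catalog — ordered class names, one per line;
* pipeline config — YAML validated against a closed key schema.

Malformed rows raise with their line number; retrograde or duplicate
timestamps are reported the same way.
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .types import (
    AlignmentOffsets,
    AnnotationTrack,
    BoundingBox,
    FrameDetections,
    InertialStream,
    WristPosition,
)

__all__ = [
    "DataFormatError",
    "ConfigError",
    "read_sensor_csv",
    "write_sensor_csv",
    "read_detections",
    "write_detections_csv",
    "write_detections_json",
    "read_annotations_csv",
    "write_annotations_csv",
    "read_offsets_csv",
    "write_offsets_csv",
    "read_catalog",
    "write_catalog",
    "PipelineConfig",
    "load_pipeline_config",
    "write_report",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class DataFormatError(ValueError):
    """A data file violates its dialect (reported with the line number)."""


class ConfigError(ValueError):
    """A configuration file fails schema validation."""


# ---------------------------------------------------------------------------
# sensor CSV

SENSOR_HEADER = ["timestamp_ms", "x", "y", "z"]


def read_sensor_csv(
    path: PathLike,
    device_id: str = "",
    position: WristPosition = WristPosition.LEFT_WRIST,
    nominal_rate_hz: float = 50.0,
) -> InertialStream:
    """Parse a sensor CSV into a validated stream.

    Device identity and wrist position come from sidecar configuration (the
    arguments), not the file itself.
    """
    path = Path(path)
    t: list[int] = []
    a: list[tuple[float, float, float]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise DataFormatError(f"{path}: empty file")
        if [h.strip() for h in header] != SENSOR_HEADER:
            raise DataFormatError(
                f"{path}: line 1: expected header {','.join(SENSOR_HEADER)}")
        prev = None
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise DataFormatError(f"{path}: line {lineno}: expected 4 fields")
            try:
                ts = int(row[0])
                xyz = (float(row[1]), float(row[2]), float(row[3]))
            except ValueError as exc:
                raise DataFormatError(f"{path}: line {lineno}: {exc}") from None
            if prev is not None:
                if ts == prev:
                    raise DataFormatError(
                        f"{path}: line {lineno}: duplicate timestamp {ts}")
                if ts < prev:
                    raise DataFormatError(
                        f"{path}: line {lineno}: retrograde timestamp {ts} < {prev}")
            prev = ts
            t.append(ts)
            a.append(xyz)
    if not t:
        raise DataFormatError(f"{path}: no samples")
    import numpy as np

    return InertialStream(device_id or path.stem, position,
                          np.array(t), np.array(a), nominal_rate_hz)


def write_sensor_csv(path: PathLike, stream: InertialStream) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SENSOR_HEADER)
        for ts, (x, y, z) in zip(stream.t, stream.a):
            w.writerow([int(ts), repr(float(x)), repr(float(y)), repr(float(z))])


# ---------------------------------------------------------------------------
# detections

DETECTION_HEADER = ["frame_index", "timestamp_ms", "class", "confidence",
                    "x_min", "y_min", "x_max", "y_max"]


def _make_box(cls: str, conf: float, x0: float, y0: float, x1: float, y1: float,
              where: str) -> Optional[BoundingBox]:
    try:
        return BoundingBox(cls, conf, x0, y0, x1, y1)
    except ValueError as exc:
        logger.warning("%s: rejected box: %s", where, exc)
        return None


def read_detections(path: PathLike, dialect: str = "csv",
                    catalog: Optional[Sequence[str]] = None
                    ) -> list[FrameDetections]:
    """Parse detection records; CSV and JSON dialects yield identical objects.

    Invalid boxes (inverted coordinates, confidence outside [0,1]) are rejected
    with a warning; classes not in the catalog warn but are kept.
    """
    path = Path(path)
    if dialect == "csv":
        frames = _read_detections_csv(path)
    elif dialect == "json":
        frames = _read_detections_json(path)
    else:
        raise ValueError("dialect must be 'csv' or 'json'")
    if catalog is not None:
        known = set(catalog)
        unknown = {b.class_label for f in frames for b in f.boxes} - known
        if unknown:
            logger.warning("%s: classes not in catalog: %s", path, sorted(unknown))
    frames.sort(key=lambda f: f.frame_t)
    prev = None
    for f in frames:
        if prev is not None and f.frame_t <= prev:
            raise DataFormatError(f"{path}: duplicate frame timestamp {f.frame_t}")
        prev = f.frame_t
    return frames


def _read_detections_csv(path: Path) -> list[FrameDetections]:
    by_frame: dict[int, FrameDetections] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise DataFormatError(f"{path}: empty file")
        if [h.strip() for h in header] != DETECTION_HEADER:
            raise DataFormatError(
                f"{path}: line 1: expected header {','.join(DETECTION_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 8:
                raise DataFormatError(f"{path}: line {lineno}: expected 8 fields")
            try:
                fi, ft = int(row[0]), int(row[1])
                cls = row[2]
                nums = [float(v) for v in row[3:]]
            except ValueError as exc:
                raise DataFormatError(f"{path}: line {lineno}: {exc}") from None
            frame = by_frame.setdefault(fi, FrameDetections(ft, fi, []))
            if cls == "":  # placeholder row for an empty frame
                continue
            box = _make_box(cls, *nums, where=f"{path}: line {lineno}")
            if box is not None:
                frame.boxes.append(box)
    return list(by_frame.values())


def _read_detections_json(path: Path) -> list[FrameDetections]:
    records = json.loads(path.read_text())
    if not isinstance(records, list):
        raise DataFormatError(f"{path}: top level must be a list of frames")
    frames = []
    for i, rec in enumerate(records):
        try:
            fd = FrameDetections(int(rec["timestamp_ms"]), int(rec["frame_index"]), [])
            for j, b in enumerate(rec.get("boxes", [])):
                box = _make_box(
                    b["class"], float(b["confidence"]),
                    float(b["x_min"]), float(b["y_min"]),
                    float(b["x_max"]), float(b["y_max"]),
                    where=f"{path}: frame record {i} box {j}")
                if box is not None:
                    fd.boxes.append(box)
        except (KeyError, TypeError, ValueError) as exc:
            raise DataFormatError(f"{path}: frame record {i}: {exc}") from None
        frames.append(fd)
    return frames


def write_detections_csv(path: PathLike, frames: Sequence[FrameDetections]) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DETECTION_HEADER)
        for f in frames:
            if not f.boxes:  # keep empty frames round-trippable
                w.writerow([f.frame_index, f.frame_t, "", 0, 0, 0, 1, 1])
            for b in f.boxes:
                w.writerow([f.frame_index, f.frame_t, b.class_label,
                            repr(b.confidence), repr(b.x_min), repr(b.y_min),
                            repr(b.x_max), repr(b.y_max)])


def write_detections_json(path: PathLike, frames: Sequence[FrameDetections]) -> None:
    records = [
        {
            "frame_index": f.frame_index,
            "timestamp_ms": f.frame_t,
            "boxes": [
                {"class": b.class_label, "confidence": b.confidence,
                 "x_min": b.x_min, "y_min": b.y_min,
                 "x_max": b.x_max, "y_max": b.y_max}
                for b in f.boxes
            ],
        }
        for f in frames
    ]
    Path(path).write_text(json.dumps(records))


# ---------------------------------------------------------------------------
# annotations, offsets, catalog

ANNOTATION_HEADER = ["start_ms", "end_ms", "class", "subject", "session"]


def read_annotations_csv(path: PathLike) -> AnnotationTrack:
    path = Path(path)
    intervals: list[tuple[int, int, str]] = []
    subject = session = ""
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ANNOTATION_HEADER:
            raise DataFormatError(
                f"{path}: line 1: expected header {','.join(ANNOTATION_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise DataFormatError(f"{path}: line {lineno}: expected 5 fields")
            try:
                intervals.append((int(row[0]), int(row[1]), row[2]))
            except ValueError as exc:
                raise DataFormatError(f"{path}: line {lineno}: {exc}") from None
            subject, session = row[3], row[4]
    try:
        return AnnotationTrack(intervals, subject, session)
    except ValueError as exc:
        raise DataFormatError(f"{path}: {exc}") from None


def write_annotations_csv(path: PathLike, track: AnnotationTrack) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ANNOTATION_HEADER)
        for s, e, c in track.intervals:
            w.writerow([s, e, c, track.subject, track.session])


def read_offsets_csv(path: PathLike) -> AlignmentOffsets:
    path = Path(path)
    offsets: dict[str, int] = {}
    reference = None
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["source", "offset_ms"]:
            raise DataFormatError(f"{path}: line 1: expected header source,offset_ms")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                offsets[row[0]] = int(row[1])
            except (IndexError, ValueError) as exc:
                raise DataFormatError(f"{path}: line {lineno}: {exc}") from None
            if reference is None and int(row[1]) == 0:
                reference = row[0]
    if reference is None:
        raise DataFormatError(f"{path}: no reference source (offset 0) found")
    return AlignmentOffsets(offsets, reference)


def write_offsets_csv(path: PathLike, offsets: AlignmentOffsets) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "offset_ms"])
        w.writerow([offsets.reference_source, 0])
        for src, off in sorted(offsets.offsets_ms.items()):
            if src != offsets.reference_source:
                w.writerow([src, off])


def read_catalog(path: PathLike) -> list[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    catalog = [ln for ln in lines if ln]
    if not catalog:
        raise DataFormatError(f"{path}: empty catalog")
    if len(set(catalog)) != len(catalog):
        raise DataFormatError(f"{path}: duplicate catalog entries")
    return catalog


def write_catalog(path: PathLike, catalog: Sequence[str]) -> None:
    Path(path).write_text("\n".join(catalog) + "\n")


# ---------------------------------------------------------------------------
# pipeline configuration

_ALLOWED_KEYS = {
    "data_dir", "catalog", "window_length_ms", "imu_overlap_frac",
    "vision_window_size", "vision_stride", "min_conf", "hand_class",
    "min_cover", "fusion_mode", "prob_mode", "protocol", "folds", "repeats",
    "train_subjects", "test_subjects", "resample_balanced", "train_fraction",
    "param_grid", "modality", "seed", "log_level", "sentinel_mode",
}


@dataclass
class PipelineConfig:
    """Validated parameters for one end-to-end run."""

    data_dir: str
    catalog: Optional[str] = None
    window_length_ms: int = 1000
    imu_overlap_frac: float = 0.75
    vision_window_size: int = 10
    vision_stride: int = 5
    min_conf: float = 0.5
    hand_class: str = "person"
    min_cover: float = 0.5
    sentinel_mode: str = "include"
    fusion_mode: str = "late"            # "early" | "late" | "imu" | "vision"
    prob_mode: str = "in_sample"
    protocol: str = "cv"                 # "cv" | "fixed-split" | "gridsearch"
    folds: int = 5
    repeats: int = 5
    train_subjects: list[str] = field(default_factory=list)
    test_subjects: list[str] = field(default_factory=list)
    resample_balanced: bool = False
    train_fraction: float = 0.8
    param_grid: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.fusion_mode not in ("early", "late", "imu", "vision"):
            raise ConfigError(f"unknown fusion_mode {self.fusion_mode!r}")
        if self.protocol not in ("cv", "fixed-split", "gridsearch"):
            raise ConfigError(f"unknown protocol {self.protocol!r}")
        if not (0 <= self.imu_overlap_frac < 1):
            raise ConfigError("imu_overlap_frac must be in [0, 1)")
        if self.window_length_ms <= 0:
            raise ConfigError("window_length_ms must be positive")
        if not (0 < self.train_fraction < 1):
            raise ConfigError("train_fraction must be in (0, 1)")


def load_pipeline_config(path: PathLike) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    if "data_dir" not in raw:
        raise ConfigError(f"{path}: data_dir is required")
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def write_report(path: PathLike, report, best_params: Optional[dict] = None) -> None:
    """Report as JSON plus a per-class CSV next to it."""
    path = Path(path)
    payload = report.to_dict()
    if best_params is not None:
        payload["best_params"] = best_params
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    report.to_frame().to_csv(path.with_suffix(".csv"), index_label="class")
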