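"""End-to-end pipeline: align -> extract (both modalities) -> match -> fuse
-> de-overlap -> evaluate.

The unit of work is a session (two wrist streams, one detection stream, one
annotation track, one offsets table). Sessions become lists of
:class:`~adlfusion.types.FusedInstance`; a cohort's instances feed one of the
three evaluation protocols.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import alignment, fusion, inertial, vision
from .evaluation import (
    NONE_CLASS,
    deoverlap_subsample,
    fixed_split_eval,
    grid_search,
    label_window,
    repeated_cv,
)
from .io import (
    PipelineConfig,
    read_annotations_csv,
    read_catalog,
    read_detections,
    read_offsets_csv,
    read_sensor_csv,
)
from .types import (
    AlignmentOffsets,
    AnnotationTrack,
    EvaluationReport,
    FrameDetections,
    FusedInstance,
    InertialStream,
    WristPosition,
)

__all__ = [
    "SessionData",
    "extract_session_instances",
    "load_cohort",
    "cohort_instances",
    "instances_to_xy",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class SessionData:
    """One session's raw inputs, in each source's native clock."""

    left: InertialStream
    right: InertialStream
    frames: list[FrameDetections]
    track: AnnotationTrack
    offsets: AlignmentOffsets


def _unify(session: SessionData) -> tuple[InertialStream, InertialStream,
                                          list[FrameDetections]]:
    off = session.offsets.offsets_ms
    left = session.left.shifted(off.get(session.left.device_id, 0))
    right = session.right.shifted(off.get(session.right.device_id, 0))
    v_off = off.get("vision", 0)
    frames = [
        FrameDetections(f.frame_t + v_off, f.frame_index, f.boxes)
        for f in session.frames
    ]
    return left, right, frames


def extract_session_instances(
    session: SessionData,
    catalog: Sequence[str],
    window_length_ms: int = 1000,
    imu_overlap_frac: float = 0.75,
    vision_window_size: int = 10,
    vision_stride: int = 5,
    min_conf: float = 0.5,
    hand_class: str = "person",
    min_cover: float = 0.5,
    sentinel_mode: str = "include",
) -> list[FusedInstance]:
    """Fused instances for one session, labeled on the vision-window grid.

    Streams and frames are shifted to the unified timeline, trimmed to the
    common span, windowed per modality, and each vision window is matched to
    the earliest inertial window starting at or after it.
    """
    left, right, frames = _unify(session)
    frame_period = int(round(1000.0 / 25.0)) if not frames else None
    if len(frames) >= 2:
        frame_period = int(frames[1].frame_t - frames[0].frame_t)
    elif frame_period is None:
        frame_period = 40
    spans = {
        "imu_left": left.span,
        "imu_right": right.span,
        "vision": (frames[0].frame_t, frames[-1].frame_t + frame_period)
        if frames else (0, 0),
    }
    t0, t1 = alignment.trim_to_common_span(spans)

    imu_grid = inertial.make_window_grid(t0, t1, window_length_ms, imu_overlap_frac)
    imu_X, imu_windows = inertial.extract_imu_features(left, right, imu_grid)

    vis_frames = [f for f in frames if t0 <= f.frame_t < t1]
    vis_X, vis_windows = vision.window_vision_features(
        vis_frames, catalog, vision_window_size, vision_stride,
        frame_period, hand_class, min_conf, sentinel_mode)

    pairs = alignment.match_all(vis_windows, imu_windows)
    instances = []
    for vi, ii in pairs:
        w = vis_windows[vi]
        instances.append(FusedInstance(
            subject=session.track.subject,
            session=session.track.session,
            window=w,
            label=label_window(w, session.track, min_cover),
            imu_features=imu_X[ii],
            vision_features=vis_X[vi],
        ))
    n_lost = len(vis_windows) - len(pairs)
    if n_lost:
        logger.info("%s/%s: dropped %d vision windows without an imu partner",
                    session.track.subject, session.track.session, n_lost)
    return instances


def extract_imu_only_instances(
    session: SessionData,
    window_length_ms: int = 1000,
    imu_overlap_frac: float = 0.75,
    min_cover: float = 0.5,
) -> list[FusedInstance]:
    """Inertial-grid instances (no vision block), labeled on the imu windows."""
    left, right, _ = _unify(session)
    t0, t1 = alignment.trim_to_common_span(
        {"imu_left": left.span, "imu_right": right.span})
    grid = inertial.make_window_grid(t0, t1, window_length_ms, imu_overlap_frac)
    X, windows = inertial.extract_imu_features(left, right, grid)
    return [
        FusedInstance(
            subject=session.track.subject, session=session.track.session,
            window=w, label=label_window(w, session.track, min_cover),
            imu_features=X[i],
        )
        for i, w in enumerate(windows)
    ]


def load_cohort(data_dir) -> tuple[list[SessionData], list[str]]:
    """Read a generated cohort directory back into session objects."""
    data_dir = Path(data_dir)
    catalog = read_catalog(data_dir / "catalog.txt")
    sessions = []
    for subj_dir in sorted(data_dir.glob("subject*")):
        for sess_dir in sorted(subj_dir.glob("session*")):
            sessions.append(SessionData(
                left=read_sensor_csv(sess_dir / "imu_left.csv", "imu_left",
                                     WristPosition.LEFT_WRIST),
                right=read_sensor_csv(sess_dir / "imu_right.csv", "imu_right",
                                      WristPosition.RIGHT_WRIST),
                frames=read_detections(sess_dir / "detections.csv", "csv", catalog),
                track=read_annotations_csv(sess_dir / "annotations.csv"),
                offsets=read_offsets_csv(sess_dir / "offsets.csv"),
            ))
    if not sessions:
        raise FileNotFoundError(f"no subject*/session* directories under {data_dir}")
    return sessions, catalog


def cohort_instances(
    sessions: Sequence[SessionData],
    catalog: Sequence[str],
    deoverlap: bool = True,
    **extract_kwargs,
) -> list[FusedInstance]:
    """Fused instances for a whole cohort, de-overlapped per session."""
    out: list[FusedInstance] = []
    for s in sessions:
        inst = extract_session_instances(s, catalog, **extract_kwargs)
        if deoverlap:
            inst = deoverlap_subsample(inst, "vision_or_fused")
        out.extend(inst)
    return out


def instances_to_xy(
    instances: Sequence[FusedInstance], modality: str = "fused"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, subjects) matrices for one modality view of the instances."""
    if modality == "fused":
        X = np.vstack([
            np.concatenate([i.imu_features, i.vision_features]) for i in instances])
    elif modality == "imu":
        X = np.vstack([i.imu_features for i in instances])
    elif modality == "vision":
        X = np.vstack([i.vision_features for i in instances])
    else:
        raise ValueError("modality must be 'fused', 'imu' or 'vision'")
    y = np.array([i.label for i in instances])
    subjects = np.array([i.subject for i in instances])
    return X, y, subjects


def _estimator_for(config: PipelineConfig, n_imu: int):
    if config.fusion_mode == "late":
        return fusion.LateFusionClassifier(
            n_imu_features=n_imu, prob_mode=config.prob_mode,
            random_state=config.seed)
    if config.fusion_mode == "early":
        return fusion.EarlyFusionClassifier(random_state=config.seed)
    if config.fusion_mode == "imu":
        return fusion.default_imu_classifier(config.seed)
    return fusion.default_vision_classifier(config.seed)


def run_pipeline(config: PipelineConfig) -> EvaluationReport:
    """Execute the configured protocol over a cohort directory."""
    sessions, catalog = load_cohort(config.data_dir)
    if config.catalog:
        catalog = read_catalog(config.catalog)
    extract_kwargs = dict(
        window_length_ms=config.window_length_ms,
        imu_overlap_frac=config.imu_overlap_frac,
        vision_window_size=config.vision_window_size,
        vision_stride=config.vision_stride,
        min_conf=config.min_conf,
        hand_class=config.hand_class,
        min_cover=config.min_cover,
        sentinel_mode=config.sentinel_mode,
    )
    if config.fusion_mode == "imu":
        instances: list[FusedInstance] = []
        for s in sessions:
            inst = extract_imu_only_instances(
                s, config.window_length_ms, config.imu_overlap_frac,
                config.min_cover)
            instances.extend(deoverlap_subsample(inst, "imu_only"))
        modality = "imu"
    else:
        instances = cohort_instances(sessions, catalog, deoverlap=True,
                                     **extract_kwargs)
        modality = {"late": "fused", "early": "fused",
                    "vision": "vision"}[config.fusion_mode]
    X, y, subjects = instances_to_xy(instances, modality)
    n_imu = instances[0].imu_features.shape[0] if modality == "fused" else 0
    estimator = _estimator_for(config, n_imu)
    class_set = sorted(set(y) | {NONE_CLASS})
    if config.protocol == "cv":
        return repeated_cv(X, y, estimator, k=config.folds,
                           repeats=config.repeats, seed=config.seed,
                           class_set=class_set)
    if config.protocol == "fixed-split":
        return fixed_split_eval(X, y, subjects, estimator,
                                config.train_subjects, config.test_subjects,
                                config.resample_balanced, config.seed,
                                class_set=class_set)
    best, report = grid_search(X, y, estimator, config.param_grid,
                               config.train_fraction, config.folds,
                               config.seed, class_set=class_set)
    report.scheme = f"gridsearch:{best}"
    return report
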