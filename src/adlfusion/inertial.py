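"""Windowed time- and frequency-domain features from wrist accelerometer streams.

The stream is cut into fixed-duration, possibly overlapping windows defined by
a timespan (not a sample count, so dropped readings shift nothing), and each
window is summarised by a 42-dimensional vector:

* per axis (x, y, z): mean, median, standard deviation, variance,
  inter-quartile range, median absolute deviation, excess kurtosis, Shannon
  entropy of the value histogram, spectral energy, spectral entropy, and the
  DC component of the DFT (11 x 3 = 33);
* Pearson correlation for the axis pairs (x,y), (x,z), (y,z) (3);
* a gravity estimate per axis from a first-order exponential low-pass (3);
* the angle between the gravity vector and each axis, in radians (3).

Feature conventions (population variance, Fisher excess kurtosis, 10-bin value
histogram for the time entropy, DC-excluded spectral energy/entropy) are the
standard ones in wearable activity recognition; degenerate cases (constant
signals, zero spectra) map to 0 so vectors stay finite for downstream learners.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import InertialStream, Modality, TemporalWindow

__all__ = [
    "AXIS_FEATURE_NAMES",
    "FEATURE_NAMES",
    "make_window_grid",
    "assign_samples",
    "time_domain_features",
    "frequency_domain_features",
    "window_features",
    "extract_imu_features",
    "feature_frame",
]

logger = logging.getLogger(__name__)

#: Per-axis feature order inside the 42-vector.
AXIS_FEATURE_NAMES = (
    "mean",
    "median",
    "std",
    "variance",
    "iqr",
    "mad",
    "kurtosis",
    "entropy_time",
    "energy",
    "entropy_freq",
    "mean_dc",
)

_AXES = ("x", "y", "z")

#: Full 42-name layout of one wrist's feature vector.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ax}_{name}" for ax in _AXES for name in AXIS_FEATURE_NAMES
) + ("corr_xy", "corr_xz", "corr_yz", "gravity_x", "gravity_y", "gravity_z",
     "orientation_x", "orientation_y", "orientation_z")

N_FEATURES_PER_WRIST = len(FEATURE_NAMES)  # 42

#: Smoothing factor of the exponential low-pass used for the gravity estimate.
GRAVITY_ALPHA = 0.9

#: Number of equal-width bins for the time-domain value-histogram entropy.
TIME_ENTROPY_BINS = 10

#: Windows with fewer samples than this are flagged invalid and dropped.
DEFAULT_MIN_SAMPLES = 4


def make_window_grid(
    span_start: int,
    span_end: int,
    length_ms: int,
    overlap_frac: float,
    modality: Modality = Modality.IMU,
) -> list[TemporalWindow]:
    """Build the sliding-window grid over ``[span_start, span_end)``.

    Windows are ``[span_start + k*S, span_start + k*S + length_ms)`` with step
    ``S = length_ms * (1 - overlap_frac)``; only windows fully inside the span
    are produced, so a span shorter than one window yields an empty grid.
    """
    if length_ms <= 0:
        raise ValueError("window length must be positive")
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError("overlap_frac must be in [0, 1)")
    if span_end <= span_start:
        raise ValueError("span_end must exceed span_start")
    step = length_ms * (1.0 - overlap_frac)
    if step <= 0:
        raise ValueError("derived step is non-positive")
    span = span_end - span_start
    if span < length_ms:
        return []
    count = int(np.floor((span - length_ms) / step)) + 1
    windows = []
    for k in range(count):
        start = int(round(span_start + k * step))
        windows.append(
            TemporalWindow(start, start + int(length_ms), index=k, modality=modality)
        )
    return windows


def assign_samples(
    window: TemporalWindow, stream: InertialStream
) -> tuple[np.ndarray, np.ndarray]:
    """Samples with ``start_ms <= t < end_ms``, in time order.

    Returns ``(t, a)`` arrays; the half-open convention puts a boundary sample
    into exactly one cell of a non-overlapping grid.
    """
    lo = int(np.searchsorted(stream.t, window.start_ms, side="left"))
    hi = int(np.searchsorted(stream.t, window.end_ms, side="left"))
    return stream.t[lo:hi], stream.a[lo:hi]


def _shannon_entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-np.sum(p * np.log(p)))


def _axis_time_features(v: np.ndarray) -> dict[str, float]:
    n = v.size
    mean = float(np.mean(v))
    median = float(np.median(v))
    var = float(np.var(v))  # population normalization
    std = float(np.sqrt(var))
    q75, q25 = np.percentile(v, [75, 25])  # linear interpolation
    iqr = float(q75 - q25)
    mad = float(np.median(np.abs(v - median)))
    if var == 0.0:
        kurt = 0.0
    else:
        # Fisher excess kurtosis with population moments
        kurt = float(np.mean((v - mean) ** 4) / var**2 - 3.0)
    vmin, vmax = float(np.min(v)), float(np.max(v))
    if vmin == vmax:
        ent = 0.0
    else:
        counts, _ = np.histogram(v, bins=TIME_ENTROPY_BINS, range=(vmin, vmax))
        ent = _shannon_entropy(counts / n)
    return {
        "mean": mean, "median": median, "std": std, "variance": var,
        "iqr": iqr, "mad": mad, "kurtosis": kurt, "entropy_time": ent,
    }


def gravity_lowpass(a: np.ndarray, alpha: float = GRAVITY_ALPHA) -> np.ndarray:
    """Last output of ``g_new = alpha*g_old + (1-alpha)*a``, seeded at a[0]."""
    g = a[0].astype(np.float64).copy()
    for row in a[1:]:
        g = alpha * g + (1.0 - alpha) * row
    return g


def time_domain_features(a: np.ndarray, min_samples: int = DEFAULT_MIN_SAMPLES
                         ) -> Optional[dict[str, float]]:
    """Time-domain block: per-axis stats, axis correlations, gravity, orientation.

    Returns ``None`` when the window has fewer than ``min_samples`` samples
    (the window is then invalid and excluded downstream).
    """
    a = np.asarray(a, dtype=np.float64)
    if a.shape[0] < min_samples:
        return None
    out: dict[str, float] = {}
    for i, ax in enumerate(_AXES):
        for name, val in _axis_time_features(a[:, i]).items():
            out[f"{ax}_{name}"] = val
    for (i, j), name in zip(((0, 1), (0, 2), (1, 2)), ("corr_xy", "corr_xz", "corr_yz")):
        vi, vj = a[:, i], a[:, j]
        si, sj = np.std(vi), np.std(vj)
        if si == 0.0 or sj == 0.0:
            out[name] = 0.0
        else:
            c = float(np.mean((vi - vi.mean()) * (vj - vj.mean())) / (si * sj))
            out[name] = float(np.clip(c, -1.0, 1.0))
    g = gravity_lowpass(a)
    norm = float(np.linalg.norm(g))
    for i, ax in enumerate(_AXES):
        out[f"gravity_{ax}"] = float(g[i])
        if norm == 0.0:
            out[f"orientation_{ax}"] = 0.0
        else:
            out[f"orientation_{ax}"] = float(np.arccos(np.clip(g[i] / norm, -1.0, 1.0)))
    return out


def frequency_domain_features(a: np.ndarray, min_samples: int = DEFAULT_MIN_SAMPLES
                              ) -> Optional[dict[str, float]]:
    """Frequency-domain block per axis: spectral energy, spectral entropy, DC mean.

    With ``X_k`` the length-N DFT of one axis: ``mean_dc = X_0/N`` (the
    arithmetic mean), ``energy = (1/N) * sum_{k>=1} |X_k|^2`` (DC excluded),
    and ``entropy_freq`` the Shannon entropy (natural log) of the normalized
    non-DC power spectrum (0 if that spectrum is all zeros).
    """
    a = np.asarray(a, dtype=np.float64)
    if a.shape[0] < min_samples:
        return None
    n = a.shape[0]
    out: dict[str, float] = {}
    spectra = np.fft.fft(a, axis=0)
    for i, ax in enumerate(_AXES):
        X = spectra[:, i]
        power = np.abs(X) ** 2
        nondc = power[1:]
        total = float(np.sum(nondc))
        out[f"{ax}_mean_dc"] = float(X[0].real / n)
        out[f"{ax}_energy"] = total / n
        out[f"{ax}_entropy_freq"] = _shannon_entropy(nondc / total) if total > 0 else 0.0
    return out


def window_features(a: np.ndarray, min_samples: int = DEFAULT_MIN_SAMPLES
                    ) -> Optional[np.ndarray]:
    """Full 42-vector for one wrist's window, ordered per FEATURE_NAMES."""
    td = time_domain_features(a, min_samples)
    if td is None:
        return None
    fd = frequency_domain_features(a, min_samples)
    assert fd is not None
    merged = {**td, **fd}
    return np.array([merged[name] for name in FEATURE_NAMES], dtype=np.float64)


def extract_imu_features(
    stream_left: InertialStream,
    stream_right: InertialStream,
    grid: Sequence[TemporalWindow],
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> tuple[np.ndarray, list[TemporalWindow]]:
    """Per-window concatenated left+right feature rows.

    One 84-dimensional row per window that is valid (>= min_samples samples)
    in *both* streams; invalid windows are dropped and logged. Returns the
    feature matrix and the list of retained windows (carrying index/times for
    alignment and labeling).
    """
    rows: list[np.ndarray] = []
    kept: list[TemporalWindow] = []
    n_dropped = 0
    for w in grid:
        _, a_left = assign_samples(w, stream_left)
        _, a_right = assign_samples(w, stream_right)
        f_left = window_features(a_left, min_samples)
        f_right = window_features(a_right, min_samples)
        if f_left is None or f_right is None:
            n_dropped += 1
            continue
        rows.append(np.concatenate([f_left, f_right]))
        kept.append(w)
    if n_dropped:
        logger.info("dropped %d windows invalid in at least one wrist stream", n_dropped)
    if not rows:
        return np.empty((0, 2 * N_FEATURES_PER_WRIST)), []
    return np.vstack(rows), kept


def feature_frame(features: np.ndarray, windows: Sequence[TemporalWindow]) -> pd.DataFrame:
    """Feature matrix as a DataFrame with window index/start/end columns."""
    cols = [f"left_{n}" for n in FEATURE_NAMES] + [f"right_{n}" for n in FEATURE_NAMES]
    df = pd.DataFrame(features, columns=cols)
    df.insert(0, "end_ms", [w.end_ms for w in windows])
    df.insert(0, "start_ms", [w.start_ms for w in windows])
    df.insert(0, "window_index", [w.index for w in windows])
    return df
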