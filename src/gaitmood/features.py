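"""Sliding-window segmentation and the 107-dimensional window feature vector.

Each walk is cut into one-second windows (24 samples at the 24 Hz default)
with 50% overlap, and every window becomes one labeled sample. Per window the
feature vector is:

* 17 time-domain statistics per axis, for the 3 accelerometer and 3
  gyroscope axes (102 features);
* the angle between the window-mean acceleration vector and each axis
  (3 features, degrees);
* the SD of the per-sample acceleration magnitude (1 feature);
* the heart rate aligned to the window (1 feature);

for 107 features in total. Statistic conventions (the common activity-
recognition choices, pinned by golden-value tests): SD is the sample SD
(n-1); energy is the mean of squares; skewness and kurtosis are
population-moment based, kurtosis excess (0 for a normal), both defined as 0
on zero-variance windows; quartiles use linear interpolation; MAD is the
unscaled median absolute deviation about the median.

Canonical column order: ``acc_x..z`` x 17 stats, ``gyro_x..z`` x 17 stats,
``angle_x..z``, ``mag_sd``, ``heart_rate``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gaitmood.preprocessing import FilterSpec, align_heart_rate, extract_walk, mean_filter
from gaitmood.sensor_io import META_COLUMNS, FeatureMatrix

log = logging.getLogger(__name__)

STAT_NAMES = [
    "mean",
    "sd",
    "max",
    "min",
    "energy",
    "kurtosis",
    "skewness",
    "rms",
    "rss",
    "sum",
    "abs_sum",
    "abs_mean",
    "range",
    "median",
    "q75",
    "q25",
    "mad",
]

AXES = ("x", "y", "z")
SENSOR_SUBSETS = ("acc", "acc+hr", "acc+gyro+hr")
#: convenient alias accepted wherever a subset name is expected
FULL_SUBSET = "acc+gyro+hr"


@dataclass
class WindowSpec:
    """Window length and hop, in samples (defaults: one second, 50% overlap)."""

    length: int = 24
    step: int = 12

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("window length must be >= 2 samples")
        if not 1 <= self.step <= self.length:
            raise ValueError("step must satisfy 1 <= step <= length")


def _normalize_subset(subset: str) -> str:
    if subset in ("full", FULL_SUBSET):
        return FULL_SUBSET
    if subset not in SENSOR_SUBSETS:
        raise ValueError(f"unknown sensor subset {subset!r}; expected {SENSOR_SUBSETS}")
    return subset


def feature_names(subset: str = FULL_SUBSET) -> list[str]:
    """Canonical ordered feature names for a sensor subset.

    Full set is 107 names; ``acc+hr`` is 56; ``acc`` is 55.
    """
    subset = _normalize_subset(subset)
    names = [f"acc_{ax}_{st}" for ax in AXES for st in STAT_NAMES]
    if subset == FULL_SUBSET:
        names += [f"gyro_{ax}_{st}" for ax in AXES for st in STAT_NAMES]
    names += [f"angle_{ax}" for ax in AXES]
    names += ["mag_sd"]
    if subset in ("acc+hr", FULL_SUBSET):
        names += ["heart_rate"]
    return names


def segment_windows(n_samples: int, spec: WindowSpec = WindowSpec()) -> list[tuple[int, int]]:
    """Half-open sample index ranges ``[k*step, k*step+length)`` fitting fully.

    The trailing partial window is discarded; an empty list is returned when
    the walk is shorter than one window.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be non-negative")
    out = []
    start = 0
    while start + spec.length <= n_samples:
        out.append((start, start + spec.length))
        start += spec.step
    return out


def _stats_matrix(windows: np.ndarray) -> np.ndarray:
    """All 17 statistics for a stack of windows, shape (n, L) -> (n, 17)."""
    w = np.asarray(windows, dtype=float)
    n, L = w.shape
    if L < 2:
        raise ValueError("windows must contain at least 2 samples")
    mean = w.mean(axis=1)
    centered = w - mean[:, None]
    m2 = np.mean(centered**2, axis=1)
    sd = w.std(axis=1, ddof=1)
    wmax = w.max(axis=1)
    wmin = w.min(axis=1)
    energy = np.mean(w**2, axis=1)
    # degenerate convention: a window whose variance is numerically zero
    # relative to its power is treated as constant (skewness = kurtosis = 0);
    # moments are taken on standardized values to avoid under/overflow
    nondeg = m2 > energy * 1e-13
    kurtosis = np.zeros(n)
    skewness = np.zeros(n)
    if np.any(nondeg):
        z = centered[nondeg] / np.sqrt(m2[nondeg])[:, None]
        skewness[nondeg] = np.mean(z**3, axis=1)
        kurtosis[nondeg] = np.mean(z**4, axis=1) - 3.0
    rms = np.sqrt(energy)
    rss = np.sqrt(np.sum(w**2, axis=1))
    total = w.sum(axis=1)
    abs_sum = np.abs(w).sum(axis=1)
    abs_mean = abs_sum / L
    rng = wmax - wmin
    median = np.median(w, axis=1)
    q75 = np.percentile(w, 75, axis=1)
    q25 = np.percentile(w, 25, axis=1)
    mad = np.median(np.abs(w - median[:, None]), axis=1)
    return np.column_stack(
        [mean, sd, wmax, wmin, energy, kurtosis, skewness, rms, rss, total,
         abs_sum, abs_mean, rng, median, q75, q25, mad]
    )


def axis_stats(window) -> dict[str, float]:
    """The 17 named statistics of a single-axis window (length >= 2)."""
    w = np.asarray(window, dtype=float)
    if w.ndim != 1:
        raise ValueError("axis_stats expects a 1-D window")
    values = _stats_matrix(w[None, :])[0]
    return dict(zip(STAT_NAMES, values.tolist()))


def angle_features(accel_window) -> np.ndarray:
    """Angles (degrees) between the window-mean acceleration and each axis.

    A zero-norm mean vector maps to 90 degrees on every axis by convention.
    """
    w = np.atleast_2d(np.asarray(accel_window, dtype=float))
    if w.shape[1] != 3:
        raise ValueError("accel window must have 3 axes")
    m = w.mean(axis=0)
    norm = np.linalg.norm(m)
    if norm == 0:
        return np.full(3, 90.0)
    return np.degrees(np.arccos(np.clip(m / norm, -1.0, 1.0)))


def magnitude_sd(accel_window) -> float:
    """Sample SD of the per-sample Euclidean norm of the acceleration."""
    w = np.asarray(accel_window, dtype=float)
    if w.ndim != 2 or w.shape[1] != 3:
        raise ValueError("accel window must have shape (L, 3)")
    if w.shape[0] < 2:
        raise ValueError("window must contain at least 2 samples")
    return float(np.linalg.norm(w, axis=1).std(ddof=1))


def build_feature_vector(accel_window, gyro_window, hr_value: float) -> np.ndarray:
    """One window's 107 features in canonical order."""
    acc = np.asarray(accel_window, dtype=float)
    gyro = np.asarray(gyro_window, dtype=float)
    if acc.shape != gyro.shape:
        raise ValueError("accelerometer and gyroscope windows must match in shape")
    if acc.ndim != 2 or acc.shape[1] != 3 or acc.shape[0] < 2:
        raise ValueError("windows must have shape (L >= 2, 3)")
    parts = [_stats_matrix(acc[:, ax][None, :])[0] for ax in range(3)]
    parts += [_stats_matrix(gyro[:, ax][None, :])[0] for ax in range(3)]
    vec = np.concatenate(
        parts + [angle_features(acc), [magnitude_sd(acc)], [float(hr_value)]]
    )
    assert vec.size == 107
    return vec


def build_dataset(
    segments,
    window_spec: WindowSpec = WindowSpec(),
    filter_spec: FilterSpec = FilterSpec(),
    sensor_subset: str = FULL_SUBSET,
) -> FeatureMatrix:
    """Windowed feature matrix for a list of walks.

    The accelerometer is mean-filtered before windowing; the gyroscope is
    used raw. Every window inherits its walk's emotion label and carries the
    participant id, its time-order index within the walk and its center time.
    Walks too short for a single window are skipped with a warning.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no walk segments supplied")
    subset = _normalize_subset(sensor_subset)
    full_names = feature_names(FULL_SUBSET)
    frames = []
    for seg in segments:
        rec = extract_walk(seg.recording, seg.start_s, seg.stop_s)
        windows = segment_windows(len(rec), window_spec)
        if not windows:
            log.warning(
                "walk %s/%s too short for one window (%d samples); skipped",
                seg.participant_id, seg.emotion, len(rec),
            )
            continue
        accel = mean_filter(rec.accel, filter_spec)
        gyro = rec.gyro
        starts = np.array([s for s, _ in windows])
        idx = starts[:, None] + np.arange(window_spec.length)
        acc_w = accel[idx]  # (n_win, L, 3)
        gyro_w = gyro[idx]
        blocks = [_stats_matrix(acc_w[:, :, ax]) for ax in range(3)]
        blocks += [_stats_matrix(gyro_w[:, :, ax]) for ax in range(3)]
        means = acc_w.mean(axis=1)  # (n_win, 3)
        norms = np.linalg.norm(means, axis=1)
        angles = np.full((len(windows), 3), 90.0)
        ok = norms > 0
        angles[ok] = np.degrees(
            np.arccos(np.clip(means[ok] / norms[ok, None], -1.0, 1.0))
        )
        mag = np.linalg.norm(acc_w, axis=2).std(axis=1, ddof=1)
        t0 = rec.timestamps[idx[:, 0]]
        t1 = rec.timestamps[idx[:, -1]]
        hr = np.array(
            [align_heart_rate(seg.heart_rate, a, b) for a, b in zip(t0, t1)]
        )
        values = np.column_stack(blocks + [angles, mag, hr])
        frame = pd.DataFrame(values, columns=full_names)
        frame.insert(0, "participant", seg.participant_id)
        frame.insert(1, "emotion", seg.emotion)
        frame.insert(2, "window_index", np.arange(len(windows)))
        frame.insert(3, "window_center_s", 0.5 * (t0 + t1))
        frames.append(frame)
    if not frames:
        raise ValueError("all supplied walks were shorter than one window")
    full = pd.concat(frames, ignore_index=True)
    names = feature_names(subset)
    return FeatureMatrix(full[META_COLUMNS + names].copy(), names)
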