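"""Signal preprocessing: smoothing, walk extraction, heart-rate alignment.

The accelerometer is smoothed with a short centered mean filter before
feature extraction; the gyroscope passes through unfiltered. Walks are cut
from recordings on half-open time intervals so adjacent cuts tile without
double-counting, and the window-level heart-rate feature is the mean of the
1 Hz samples falling inside the window's time span (nearest sample when the
span contains none).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gaitmood.sensor_io import HeartRateSeries, SensorRecording


@dataclass
class FilterSpec:
    kind: str = "mean"
    width: int = 3

    def __post_init__(self) -> None:
        if self.kind != "mean":
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError("filter width must be a positive odd sample count")


class EmptySegmentError(ValueError):
    """A requested cut contains no samples."""


def mean_filter(signal, spec: FilterSpec | int = 3) -> np.ndarray:
    """Centered moving average with truncated (shrunken) edge windows.

    Output length equals input length; the filter is linear, preserves
    constants, and at the edges averages only the samples that exist rather
    than padding. Works on 1-D signals or on ``(n, k)`` channel stacks
    (filtered along axis 0).
    """
    if isinstance(spec, int):
        spec = FilterSpec(width=spec)
    x = np.asarray(signal, dtype=float)
    if x.shape[0] < 1:
        raise ValueError("signal must contain at least one sample")
    if spec.width == 1:
        return x.copy()
    half = spec.width // 2
    n = x.shape[0]
    # cumulative-sum formulation: window [i-half, i+half] clipped to the signal
    zeros = np.zeros((1,) + x.shape[1:])
    csum = np.concatenate([zeros, np.cumsum(x, axis=0)], axis=0)
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    sums = csum[hi] - csum[lo]
    counts = (hi - lo).astype(float)
    counts = counts.reshape((n,) + (1,) * (x.ndim - 1))
    return sums / counts


def extract_walk(recording: SensorRecording, start_s: float, stop_s: float) -> SensorRecording:
    """Cut a recording to the half-open interval ``[start_s, stop_s)``.

    Timestamps are re-zeroed to the cut start. An empty result raises
    :class:`EmptySegmentError` rather than returning a degenerate recording.
    """
    if not start_s < stop_s:
        raise ValueError("start_s must precede stop_s")
    t = recording.timestamps
    mask = (t >= start_s) & (t < stop_s)
    if not np.any(mask):
        raise EmptySegmentError(
            f"no samples in [{start_s}, {stop_s}) "
            f"(recording spans [{t[0]}, {t[-1]}])"
        )
    return SensorRecording(
        timestamps=t[mask] - start_s,
        accel=recording.accel[mask],
        gyro=recording.gyro[mask],
        nominal_rate=recording.nominal_rate,
    )


def align_heart_rate(hr: HeartRateSeries, start_s: float, stop_s: float) -> float:
    """Heart-rate value for a motion window spanning ``[start_s, stop_s]``.

    Mean of the samples inside the (closed) span; if the span contains no
    sample, the sample nearest to the window center is used.
    """
    if len(hr) < 1:
        raise ValueError("heart-rate series is empty")
    mask = (hr.timestamps >= start_s) & (hr.timestamps <= stop_s)
    if np.any(mask):
        return float(np.mean(hr.bpm[mask]))
    center = 0.5 * (start_s + stop_s)
    return float(hr.bpm[int(np.argmin(np.abs(hr.timestamps - center)))])
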