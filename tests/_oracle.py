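"""Brute-force reference implementations of the window features.

Deliberately written with plain Python (``math``/``statistics``), independent
of the vectorized numpy code they check.
"""

import math
import statistics


def _quantile(xs, p):
    """Linear-interpolation quantile on a sorted list."""
    n = len(xs)
    h = (n - 1) * p
    lo = math.floor(h)
    if lo + 1 >= n:
        return xs[-1]
    return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])


def oracle_axis_stats(window):
    xs = [float(v) for v in window]
    n = len(xs)
    mean = sum(xs) / n
    m2 = sum((v - mean) ** 2 for v in xs) / n
    m3 = sum((v - mean) ** 3 for v in xs) / n
    m4 = sum((v - mean) ** 4 for v in xs) / n
    energy = sum(v * v for v in xs) / n
    srt = sorted(xs)
    med = statistics.median(xs)
    return {
        "mean": mean,
        "sd": statistics.stdev(xs),
        "max": max(xs),
        "min": min(xs),
        "energy": energy,
        "kurtosis": (m4 / m2**2 - 3.0) if m2 > 0 else 0.0,
        "skewness": (m3 / m2**1.5) if m2 > 0 else 0.0,
        "rms": math.sqrt(energy),
        "rss": math.sqrt(sum(v * v for v in xs)),
        "sum": sum(xs),
        "abs_sum": sum(abs(v) for v in xs),
        "abs_mean": sum(abs(v) for v in xs) / n,
        "range": max(xs) - min(xs),
        "median": med,
        "q75": _quantile(srt, 0.75),
        "q25": _quantile(srt, 0.25),
        "mad": statistics.median([abs(v - med) for v in xs]),
    }


def oracle_angles(accel_window):
    mean = [sum(row[ax] for row in accel_window) / len(accel_window) for ax in range(3)]
    norm = math.sqrt(sum(m * m for m in mean))
    if norm == 0:
        return [90.0, 90.0, 90.0]
    return [math.degrees(math.acos(max(-1.0, min(1.0, m / norm)))) for m in mean]


def oracle_magnitude_sd(accel_window):
    norms = [math.sqrt(sum(v * v for v in row)) for row in accel_window]
    return statistics.stdev(norms)
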