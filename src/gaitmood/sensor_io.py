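"""Reading, writing and in-memory containers for sensor sessions.

On-disk formats (all plain text, UTF-8, comma-separated, ``.`` decimal,
mandatory header row):

* sensor log CSV with columns ``t,ax,ay,az,gx,gy,gz`` — time in seconds since
  session start, accelerometer in m/s^2, gyroscope in deg/s;
* heart-rate CSV with columns ``t,bpm``;
* session manifest JSON listing one walk per (participant, emotion) with its
  condition, presentation order, start/stop times and file references;
* feature-matrix CSV: metadata columns followed by the canonical feature
  columns (see :mod:`gaitmood.features` for the naming contract).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EMOTIONS = ("happy", "neutral", "sad")
CONDITIONS = (1, 2, 3)

SENSOR_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
HR_COLUMNS = ["t", "bpm"]

#: metadata columns of a feature matrix, in order, before the feature columns
META_COLUMNS = ["participant", "emotion", "window_index", "window_center_s"]


class FormatError(ValueError):
    """A file violates the on-disk schema (missing columns, bad rows...)."""


class SchemaError(FormatError):
    """A feature matrix does not carry a recognised canonical column set."""


@dataclass
class SensorRecording:
    """Timestamped triaxial accelerometer + gyroscope streams for one session.

    ``accel`` and ``gyro`` are float arrays of shape ``(n, 3)`` (axes x, y, z);
    ``timestamps`` is strictly increasing, in seconds.
    """

    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    nominal_rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.timestamps.shape[0]
        if n < 1:
            raise ValueError("recording must contain at least one sample")
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                f"channel shape mismatch: {n} timestamps, "
                f"accel {self.accel.shape}, gyro {self.gyro.shape}"
            )
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            bad = int(np.flatnonzero(np.diff(self.timestamps) <= 0)[0]) + 1
            raise ValueError(f"timestamps not strictly increasing at sample {bad}")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")

    def __len__(self) -> int:
        return int(self.timestamps.shape[0])


@dataclass
class HeartRateSeries:
    """Heart-rate samples (bpm) on their own, typically 1 Hz, time base."""

    timestamps: np.ndarray
    bpm: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.timestamps.shape != self.bpm.shape or self.timestamps.ndim != 1:
            raise ValueError("timestamps and bpm must be 1-D arrays of equal length")
        if self.timestamps.size < 1:
            raise ValueError("heart-rate series must be non-empty")
        if np.any(self.bpm <= 0):
            raise ValueError("bpm values must be positive")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("heart-rate timestamps not strictly increasing")

    def __len__(self) -> int:
        return int(self.timestamps.size)


@dataclass
class WalkSegment:
    """One labeled walk: a recording slice plus its heart-rate series."""

    participant_id: str
    condition: int
    emotion: str
    start_s: float
    stop_s: float
    recording: SensorRecording
    heart_rate: HeartRateSeries

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise ValueError(
                f"unknown emotion label {self.emotion!r}; expected one of {EMOTIONS}"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if not self.start_s < self.stop_s:
            raise ValueError(
                f"start_s ({self.start_s}) must precede stop_s ({self.stop_s})"
            )


@dataclass
class FeatureMatrix:
    """Windowed feature vectors with labels and bookkeeping metadata.

    ``frame`` holds the metadata columns (:data:`META_COLUMNS`) followed by the
    feature columns in canonical order.
    """

    frame: pd.DataFrame
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature matrix missing metadata columns {missing}")
        if not self.feature_names:
            self.feature_names = [
                c for c in self.frame.columns if c not in META_COLUMNS
            ]
        for name in self.feature_names:
            if name not in self.frame.columns:
                raise ValueError(f"declared feature column {name!r} absent from frame")

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["emotion"].to_numpy()

    @property
    def class_counts(self) -> dict[str, int]:
        return self.frame["emotion"].value_counts().to_dict()

    def __len__(self) -> int:
        return len(self.frame)

    def select_labels(self, labels) -> "FeatureMatrix":
        """Restrict to rows whose emotion is in ``labels`` (e.g. happy vs sad)."""
        sub = self.frame[self.frame["emotion"].isin(list(labels))].reset_index(
            drop=True
        )
        return FeatureMatrix(sub, list(self.feature_names))

    def select_features(self, names) -> "FeatureMatrix":
        names = list(names)
        cols = META_COLUMNS + names
        return FeatureMatrix(self.frame[cols].copy(), names)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_csv_checked(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in required_columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(values.isna().to_numpy())
        if bad.size:
            # +2: header line plus 1-based indexing
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} at row {bad[0] + 2}"
            )
        df[col] = values
    return df


def read_sensor_csv(path, nominal_rate: float = 24.0) -> SensorRecording:
    """Read a ``t,ax,ay,az,gx,gy,gz`` sensor log into a :class:`SensorRecording`."""
    df = _read_csv_checked(path, SENSOR_COLUMNS)
    t = df["t"].to_numpy(dtype=float)
    if t.size > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise FormatError(
                f"{path}: timestamps not strictly increasing at row {bad[0] + 3}"
            )
    return SensorRecording(
        timestamps=t,
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        nominal_rate=nominal_rate,
    )


def write_sensor_csv(recording: SensorRecording, path) -> None:
    df = pd.DataFrame(
        np.column_stack([recording.timestamps, recording.accel, recording.gyro]),
        columns=SENSOR_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_heart_rate_csv(path) -> HeartRateSeries:
    df = _read_csv_checked(path, HR_COLUMNS)
    return HeartRateSeries(
        timestamps=df["t"].to_numpy(dtype=float), bpm=df["bpm"].to_numpy(dtype=float)
    )


def write_heart_rate_csv(hr: HeartRateSeries, path) -> None:
    pd.DataFrame({"t": hr.timestamps, "bpm": hr.bpm}).to_csv(path, index=False)


def write_session(segments, out_dir, nominal_rate: float = 24.0) -> Path:
    """Write a list of :class:`WalkSegment` as CSVs plus a JSON manifest.

    Returns the manifest path. File names encode participant and emotion so a
    directory listing reads like the session log.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    walks = []
    for order, seg in enumerate(segments):
        stem = f"{seg.participant_id}_{seg.emotion}"
        sensor_file = f"{stem}_imu.csv"
        hr_file = f"{stem}_hr.csv"
        write_sensor_csv(seg.recording, out_dir / sensor_file)
        write_heart_rate_csv(seg.heart_rate, out_dir / hr_file)
        walks.append(
            {
                "participant": seg.participant_id,
                "condition": seg.condition,
                "emotion": seg.emotion,
                "order": order,
                "start_s": seg.start_s,
                "stop_s": seg.stop_s,
                "sensor_file": sensor_file,
                "hr_file": hr_file,
            }
        )
    manifest = {"nominal_rate_hz": nominal_rate, "walks": walks}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_session(manifest_path) -> list[WalkSegment]:
    """Load all walks referenced by a session manifest.

    Labels are taken verbatim from the manifest and validated against the
    closed emotion set; start/stop ordering and file existence are checked
    before any heavy parsing.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    rate = float(manifest.get("nominal_rate_hz", 24.0))
    segments = []
    for entry in manifest["walks"]:
        emotion = entry["emotion"]
        if emotion not in EMOTIONS:
            raise FormatError(
                f"{manifest_path}: unknown emotion label {emotion!r} for "
                f"participant {entry.get('participant')!r}"
            )
        if not float(entry["start_s"]) < float(entry["stop_s"]):
            raise FormatError(
                f"{manifest_path}: start_s >= stop_s for participant "
                f"{entry.get('participant')!r} ({emotion})"
            )
        for key in ("sensor_file", "hr_file"):
            if not (base / entry[key]).exists():
                raise FormatError(
                    f"{manifest_path}: dangling file reference {entry[key]!r}"
                )
        segments.append(
            WalkSegment(
                participant_id=str(entry["participant"]),
                condition=int(entry["condition"]),
                emotion=emotion,
                start_s=float(entry["start_s"]),
                stop_s=float(entry["stop_s"]),
                recording=read_sensor_csv(base / entry["sensor_file"], rate),
                heart_rate=read_heart_rate_csv(base / entry["hr_file"]),
            )
        )
    return segments


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    cols = META_COLUMNS + list(matrix.feature_names)
    matrix.frame[cols].to_csv(path, index=False)


def read_feature_matrix(path) -> FeatureMatrix:
    """Read a feature-matrix CSV, validating the canonical column contract.

    The feature columns (everything after the metadata columns) must match one
    of the canonical sensor subsets exactly, in order.
    """
    from gaitmood.features import SENSOR_SUBSETS, feature_names as canonical_names

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing metadata columns {missing}")
    found = [c for c in df.columns if c not in META_COLUMNS]
    for subset in SENSOR_SUBSETS:
        if found == canonical_names(subset):
            return FeatureMatrix(df, found)
    raise SchemaError(
        f"{path}: feature columns ({len(found)}) do not match any canonical "
        f"subset {[len(canonical_names(s)) for s in SENSOR_SUBSETS]}"
    )
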