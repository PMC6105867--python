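"""Seeded synthetic cohorts of walking IMU + heart-rate data.

No raw data from the original study are available, so this module generates
cohorts with the statistical structure the downstream analysis assumes:

* each participant walks once per emotion (happy / neutral / sad) under one
  of three study conditions, with presentation order counterbalanced
  (sad-first for even participant indices);
* wrist motion is modelled per axis as a sum of the first three harmonics of
  the step frequency (cadence), plus white sensor noise and a slow
  random-walk drift that induces within-walk autocorrelation. The phase
  structure across axes and harmonics is a per-participant gait signature:
  all of a participant's walks share it and differ only by a global time
  offset, so windowed-statistic distributions are identical across walks
  unless an emotion effect moves them;
* emotion modulates cadence (additive), arm-swing amplitude (multiplicative)
  and heart rate (additive). How strongly — and in which direction — each
  participant expresses those effects is idiosyncratic (random per-user
  magnitude and sign), and each participant wears the watch at their own
  wrist orientation (a random rotation of the motion axes). Personal
  idiosyncrasy therefore dominates the emotion effect: the regime in which
  personal models work and cross-user models sit near chance;
* heart rate is an AR(1) series around the participant's emotional set point
  plus a per-walk session-arousal offset, sampled at 1 Hz independently of
  the IMU rate.

Everything is reproducible from ``CohortConfig.seed``; per-participant
substreams are keyed by participant index so cohorts can be generated in any
order or in parallel.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from gaitmood.sensor_io import EMOTIONS, HeartRateSeries, SensorRecording, WalkSegment

# population-level defaults for an adult walking at a comfortable pace with a
# watch on the wrist; amplitudes in m/s^2 (accelerometer) and deg/s (gyro)
BASE_CADENCE_HZ = 1.8
BASE_SWING_AMP = 2.0
BASE_HARMONIC_WEIGHTS = (1.0, 0.4, 0.2)
BASE_NOISE_SD = 1.2
BASE_DRIFT_SD = 0.01
BASE_HR_MEAN = 100.0
BASE_HR_SD = 8.0
BASE_HR_PHI = 0.9

#: relative arm-swing energy per accelerometer axis (x along the forearm)
ACC_AXIS_SCALE = (1.0, 0.65, 0.45)
#: gyroscope amplitude per unit accelerometer amplitude (deg/s per m/s^2)
GYRO_RATIO = 25.0
GYRO_AXIS_SCALE = (1.0, 0.8, 0.5)
#: between-user heart-rate SD per unit of ``between_user_sd``
HR_BETWEEN_SCALE = 40.0
#: per-participant phase dispersion (radians) per unit of ``between_user_sd``
PHASE_SCALE = 2.0 * np.pi
#: probability per unit of ``between_user_sd`` that a participant expresses an
#: emotion effect with inverted sign (capped at 0.5: direction fully
#: idiosyncratic). Emotion expression that is real within a user but
#: directionally inconsistent across users is what makes personal models work
#: while cross-user transfer sits at chance.
EFFECT_SIGN_FLIP_RATE = 5.0 / 3.0
#: wrist-pose rotation dispersion (radians per axis) per unit of
#: ``between_user_sd``: every participant wears the watch at their own
#: orientation, so axis-level features do not correspond across users
ROTATION_SCALE = np.pi

# population-mean waveform shape: fixed (arbitrary, asymmetric) phases of
# harmonics 1-3 per axis. The phase STRUCTURE is a participant-level gait
# signature — walks of one participant share it and differ only by a global
# time offset, so windowed-statistic distributions are identical across that
# participant's walks unless an emotion effect moves them.
BASE_ACC_PHASES = ((0.0, 0.7, 1.9), (2.1, 4.0, 0.3), (4.4, 2.6, 5.1))
BASE_GYRO_PHASES = ((1.3, 3.3, 0.2), (5.0, 1.1, 2.8), (3.7, 5.6, 4.9))


@dataclass
class GaitParams:
    """Per-participant gait and heart-rate parameters.

    ``acc_phases`` / ``gyro_phases`` hold the per-axis, per-harmonic phase
    offsets that define the participant's waveform shape. The
    ``effect_scale_*`` fields modulate how strongly (and in which direction)
    the cohort-level emotion effect expresses in this participant — the
    between-user heterogeneity that makes cross-user models fail.
    """

    cadence_hz: float = BASE_CADENCE_HZ
    swing_amp: float = BASE_SWING_AMP
    harmonic_weights: tuple[float, ...] = BASE_HARMONIC_WEIGHTS
    noise_sd: float = BASE_NOISE_SD
    drift_sd: float = BASE_DRIFT_SD
    hr_mean: float = BASE_HR_MEAN
    hr_sd: float = BASE_HR_SD
    hr_phi: float = BASE_HR_PHI
    #: SD (bpm) of the per-walk heart-rate level offset (session arousal)
    hr_walk_sd: float = 10.0
    acc_phases: tuple = BASE_ACC_PHASES
    gyro_phases: tuple = BASE_GYRO_PHASES
    effect_scale_cadence: float = 1.0
    effect_scale_amp: float = 1.0
    effect_scale_hr: float = 1.0
    #: wrist-pose rotation applied to both motion sensors (3x3, row tuples)
    orientation: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    def __post_init__(self) -> None:
        if self.cadence_hz <= 0:
            raise ValueError("cadence_hz must be positive")
        if self.swing_amp < 0 or self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("amplitudes and noise SDs must be non-negative")
        if not 40.0 <= self.hr_mean <= 220.0:
            raise ValueError("hr_mean must lie in [40, 220] bpm")
        if not 0.0 <= self.hr_phi < 1.0:
            raise ValueError("hr_phi must lie in [0, 1)")


@dataclass
class EmotionEffect:
    """How each emotion shifts gait and heart rate relative to neutral.

    ``d_cadence`` is an additive step-frequency shift (Hz), ``d_amp`` a
    multiplicative arm-swing factor, ``d_hr`` an additive heart-rate shift
    (bpm). Neutral is the reference (all effects zero / one).
    """

    d_cadence: dict = field(
        default_factory=lambda: {"happy": 0.15, "neutral": 0.0, "sad": -0.15}
    )
    d_amp: dict = field(
        default_factory=lambda: {"happy": 1.15, "neutral": 1.0, "sad": 0.85}
    )
    d_hr: dict = field(
        default_factory=lambda: {"happy": 6.0, "neutral": 0.0, "sad": -6.0}
    )

    def __post_init__(self) -> None:
        for table in (self.d_cadence, self.d_amp, self.d_hr):
            missing = [e for e in EMOTIONS if e not in table]
            if missing:
                raise ValueError(f"emotion effect missing entries for {missing}")
        if self.d_cadence["neutral"] != 0.0 or self.d_hr["neutral"] != 0.0:
            raise ValueError("neutral effects must be zero by convention")
        if self.d_amp["neutral"] != 1.0:
            raise ValueError("neutral amplitude factor must be 1 by convention")

    @classmethod
    def zero(cls) -> "EmotionEffect":
        """No emotion effect at all (null / type-I configuration)."""
        return cls(
            d_cadence={e: 0.0 for e in EMOTIONS},
            d_amp={e: 1.0 for e in EMOTIONS},
            d_hr={e: 0.0 for e in EMOTIONS},
        )

    @classmethod
    def hr_only(cls, d_hr: float = 8.0) -> "EmotionEffect":
        """Heart rate separates emotions; motion does not."""
        return cls(
            d_cadence={e: 0.0 for e in EMOTIONS},
            d_amp={e: 1.0 for e in EMOTIONS},
            d_hr={"happy": d_hr, "neutral": 0.0, "sad": -d_hr},
        )


@dataclass
class CohortConfig:
    """Shape and statistical conditions of a simulated cohort.

    Defaults are sized so each emotion walk yields roughly 400 one-second
    windows at 50% overlap (202 s at 24 Hz -> 403 windows), with a small
    between-walk duration jitter reproducing the study-like spread of
    per-emotion window counts.
    """

    n_participants: int = 14
    condition: int = 1
    walk_duration_s: float = 202.0
    duration_jitter_s: float = 10.0
    sample_rate_hz: float = 24.0
    between_user_sd: float = 0.5
    emotion_effect: EmotionEffect = field(default_factory=EmotionEffect)
    seed: int = 0
    #: applied on top of each drawn GaitParams (e.g. {"drift_sd": 0.0})
    param_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.walk_duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("walk_duration_s and sample_rate_hz must be positive")
        if self.condition not in (1, 2, 3):
            raise ValueError("condition must be 1, 2 or 3")
        if self.between_user_sd < 0 or self.duration_jitter_s < 0:
            raise ValueError("SDs must be non-negative")


def null_cohort_config(n_participants: int = 14, seed: int = 0, **kwargs) -> CohortConfig:
    """Cohort in which happy and sad walks are statistically exchangeable.

    Besides zeroing the emotion effects this disables the slow drift and the
    heart-rate persistence: any walk-level random effect (a drift realisation,
    a persistent AR(1) excursion) would let a classifier tell the two walks
    apart even with no emotion effect, so the correct chance-level expectation
    only holds when windows are exchangeable across walks.
    """
    return CohortConfig(
        n_participants=n_participants,
        emotion_effect=EmotionEffect.zero(),
        seed=seed,
        param_overrides={"drift_sd": 0.0, "hr_phi": 0.0, "hr_walk_sd": 0.0},
        **kwargs,
    )


def hr_dominant_cohort_config(
    n_participants: int = 14, seed: int = 0, d_hr: float = 8.0, **kwargs
) -> CohortConfig:
    """Cohort where heart rate carries the entire emotion signal."""
    return CohortConfig(
        n_participants=n_participants,
        emotion_effect=EmotionEffect.hr_only(d_hr),
        seed=seed,
        param_overrides={"drift_sd": 0.0},
        **kwargs,
    )


def _participant_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    # substream keyed by (root seed, participant, stream); independent and
    # reproducible regardless of generation order
    return np.random.default_rng([seed & 0x7FFFFFFF, index, stream])


def participant_index(participant_id: str) -> int:
    """Inverse of the ``p{index:02d}`` naming used by :func:`simulate_cohort`."""
    return int(str(participant_id).lstrip("p"))


def draw_participant_params(
    config: CohortConfig, participant_id, rng: np.random.Generator | None = None
) -> GaitParams:
    """Draw one participant's :class:`GaitParams` around the population means.

    Deterministic given ``(config.seed, participant_id)``. ``between_user_sd``
    is the SD of the cadence draw; amplitude and harmonic weights vary
    log-normally with the same sigma and the heart-rate level with
    ``HR_BETWEEN_SCALE`` times it, so ``between_user_sd == 0`` degenerates to
    identical population-mean participants.
    """
    index = (
        participant_id
        if isinstance(participant_id, (int, np.integer))
        else participant_index(participant_id)
    )
    if rng is None:
        rng = _participant_rng(config.seed, int(index), stream=0)
    sd = config.between_user_sd
    cadence = float(np.clip(BASE_CADENCE_HZ + sd * rng.standard_normal(), 0.5, 4.0))
    swing = BASE_SWING_AMP * float(np.exp(sd * rng.standard_normal()))
    weights = tuple(
        w * float(np.exp(sd * z))
        for w, z in zip(BASE_HARMONIC_WEIGHTS, rng.standard_normal(3))
    )
    hr_mean = float(
        np.clip(BASE_HR_MEAN + HR_BETWEEN_SCALE * sd * rng.standard_normal(), 40, 220)
    )
    acc_phases = tuple(
        tuple((np.asarray(row) + PHASE_SCALE * sd * rng.standard_normal(3)) % (2 * np.pi))
        for row in BASE_ACC_PHASES
    )
    gyro_phases = tuple(
        tuple((np.asarray(row) + PHASE_SCALE * sd * rng.standard_normal(3)) % (2 * np.pi))
        for row in BASE_GYRO_PHASES
    )
    # per-user emotion expression: log-normal magnitude around the nominal
    # effect, with an idiosyncratic direction (sign) per channel
    magnitudes = np.exp(sd * rng.standard_normal(3))
    flip_p = min(0.5, EFFECT_SIGN_FLIP_RATE * sd)
    signs = np.where(rng.random(3) < flip_p, -1.0, 1.0)
    scale_c, scale_a, scale_h = signs * magnitudes
    rotvec = ROTATION_SCALE * sd * rng.standard_normal(3)
    orientation = tuple(map(tuple, Rotation.from_rotvec(rotvec).as_matrix()))
    params = GaitParams(
        cadence_hz=cadence,
        swing_amp=swing,
        harmonic_weights=weights,
        hr_mean=hr_mean,
        acc_phases=acc_phases,
        gyro_phases=gyro_phases,
        effect_scale_cadence=float(scale_c),
        effect_scale_amp=float(scale_a),
        effect_scale_hr=float(scale_h),
        orientation=orientation,
    )
    if config.param_overrides:
        params = replace(params, **config.param_overrides)
    return params


def synthesize_walk(
    params: GaitParams,
    effect: EmotionEffect,
    emotion: str,
    duration_s: float,
    rate_hz: float,
    rng: np.random.Generator,
) -> tuple[SensorRecording, HeartRateSeries]:
    """Generate one emotion-labeled walk for one participant.

    Each motion axis is a sum of harmonics at the emotion-shifted cadence,
    with the participant's per-axis, per-harmonic phase structure shifted by
    one global per-walk time offset, scaled by the emotion-adjusted
    amplitude, plus white noise and a random-walk drift. Heart rate is an
    AR(1) series around ``hr_mean + d_hr`` at 1 Hz. Emotion effects are
    modulated by the participant's ``effect_scale_*`` fields.
    """
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion {emotion!r}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")

    n = int(round(duration_s * rate_hz))
    if n < 1:
        raise ValueError("duration too short for a single sample")
    t = np.arange(n) / rate_hz
    freq = max(
        params.cadence_hz + params.effect_scale_cadence * effect.d_cadence[emotion],
        0.2,
    )
    amp = params.swing_amp * effect.d_amp[emotion] ** params.effect_scale_amp
    # one global time offset per walk; the waveform shape (relative phases)
    # stays the participant's, so walks differ only where emotion moves them
    offset = rng.uniform(0.0, 1.0 / freq)

    def _channels(axis_scale, phases, gain: float) -> np.ndarray:
        out = np.empty((n, 3))
        for ax in range(3):
            signal = np.zeros(n)
            for h, w in enumerate(params.harmonic_weights, start=1):
                signal += w * amp * gain * axis_scale[ax] * np.sin(
                    2.0 * np.pi * h * freq * (t + offset) + phases[ax][h - 1]
                )
            if params.noise_sd > 0:
                signal = signal + gain * params.noise_sd * rng.standard_normal(n)
            if params.drift_sd > 0:
                signal = signal + np.cumsum(
                    gain * params.drift_sd * rng.standard_normal(n)
                )
            out[:, ax] = signal
        return out

    accel = _channels(ACC_AXIS_SCALE, params.acc_phases, 1.0)
    gyro = _channels(GYRO_AXIS_SCALE, params.gyro_phases, GYRO_RATIO)
    R = np.asarray(params.orientation, dtype=float)
    if not np.allclose(R, np.eye(3)):
        accel = accel @ R.T
        gyro = gyro @ R.T
    recording = SensorRecording(
        timestamps=t, accel=accel, gyro=gyro, nominal_rate=rate_hz
    )

    n_hr = max(int(np.ceil(duration_s)), 1)
    mu = params.hr_mean + params.effect_scale_hr * effect.d_hr[emotion]
    if params.hr_walk_sd > 0:
        mu = mu + params.hr_walk_sd * rng.standard_normal()
    hr = np.empty(n_hr)
    hr[0] = mu + params.hr_sd * rng.standard_normal()
    innov_sd = params.hr_sd * np.sqrt(max(1.0 - params.hr_phi**2, 0.0))
    for k in range(1, n_hr):
        hr[k] = mu + params.hr_phi * (hr[k - 1] - mu) + innov_sd * rng.standard_normal()
    hr = np.clip(hr, 30.0, None)
    heart = HeartRateSeries(timestamps=np.arange(n_hr, dtype=float), bpm=hr)
    return recording, heart


def simulate_cohort(config: CohortConfig) -> list[WalkSegment]:
    """Simulate a full cohort: three emotion walks per participant.

    Emotion order is counterbalanced by participant parity (sad first for even
    indices, happy first for odd), with the neutral walk always between the
    two emotional walks as a washout. Fully reproducible from ``config.seed``.
    """
    segments: list[WalkSegment] = []
    for i in range(config.n_participants):
        params = draw_participant_params(config, i)
        order = ["sad", "neutral", "happy"] if i % 2 == 0 else ["happy", "neutral", "sad"]
        for j, emotion in enumerate(order):
            rng = _participant_rng(config.seed, i, stream=1 + j)
            duration = config.walk_duration_s
            if config.duration_jitter_s > 0:
                duration = float(
                    np.clip(
                        duration + config.duration_jitter_s * rng.standard_normal(),
                        10.0,
                        None,
                    )
                )
            recording, heart = synthesize_walk(
                params,
                config.emotion_effect,
                emotion,
                duration,
                config.sample_rate_hz,
                rng,
            )
            segments.append(
                WalkSegment(
                    participant_id=f"p{i:02d}",
                    condition=config.condition,
                    emotion=emotion,
                    start_s=0.0,
                    stop_s=float(recording.timestamps[-1] + 1.0 / config.sample_rate_hz),
                    recording=recording,
                    heart_rate=heart,
                )
            )
    return segments


def config_from_dict(raw: dict) -> CohortConfig:
    """Build a :class:`CohortConfig` from a plain (YAML-friendly) mapping."""
    raw = copy.deepcopy(raw)
    effect = raw.pop("emotion_effect", None)
    if isinstance(effect, dict):
        raw["emotion_effect"] = EmotionEffect(**effect)
    elif isinstance(effect, str):
        factory = {"default": EmotionEffect, "zero": EmotionEffect.zero,
                   "hr_only": EmotionEffect.hr_only}[effect]
        raw["emotion_effect"] = factory()
    return CohortConfig(**raw)
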