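import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitmood as gm

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two participants, short walks: cheap segments for unit tests."""
    config = gm.CohortConfig(
        n_participants=2, walk_duration_s=30.0, duration_jitter_s=0.0, seed=7
    )
    return gm.simulate_cohort(config)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_cohort):
    return gm.build_dataset(tiny_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_walk_segment(n, emotion="happy", pid="p00", rate=24.0, seed=0):
    """A noise-only walk of exactly n samples, for bookkeeping tests."""
    from gaitmood.sensor_io import HeartRateSeries, SensorRecording, WalkSegment

    gen = np.random.default_rng(seed)
    t = np.arange(n) / rate
    rec = SensorRecording(t, gen.normal(size=(n, 3)), gen.normal(size=(n, 3)), rate)
    n_hr = max(int(n / rate), 1)
    hr = HeartRateSeries(np.arange(n_hr, dtype=float), np.full(n_hr, 80.0))
    return WalkSegment(pid, 1, emotion, 0.0, n / rate, rec, hr)
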