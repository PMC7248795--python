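from datetime import datetime

import pytest
from hypothesis import HealthCheck, settings

from stimtrack import DetectorConfig, SessionRecord, StimulationProfile

settings.register_profile(
    "default",
    settings(
        derandomize=True,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("default")


@pytest.fixture
def square_profile() -> StimulationProfile:
    """Noise-free square duty cycle: 10 s on at 50 units, 10 s off."""
    return StimulationProfile(
        contraction_duration=10.0,
        relaxation_duration=10.0,
        amplitude=50.0,
        ramp_time=0.0,
        baseline_noise_sd=0.0,
        sample_rate=100.0,
    )


@pytest.fixture
def detector() -> DetectorConfig:
    return DetectorConfig(
        on_threshold=10.0,
        off_threshold=5.0,
        session_gap_timeout=120.0,
        min_session_duration=60.0,
    )


def make_record(
    start: str = "2024-01-02T09:00:00",
    end: str = "2024-01-02T10:00:00",
    voltage: float = 36.0,
) -> SessionRecord:
    return SessionRecord(
        datetime.fromisoformat(start), datetime.fromisoformat(end), voltage
    )


def brute_force_sessions(samples, sample_rate, config):
    """Independent per-sample scan implementing the detection rule directly.

    A session opens at the first sample >= on_threshold, stays open while
    samples >= off_threshold keep arriving within the gap timeout, closes
    at the last such sample, and is kept only if its span meets the
    minimum duration.
    """
    sessions = []
    start = last = None
    for i, v in enumerate(samples):
        if start is None:
            if v >= config.on_threshold:
                start = last = i
        elif v >= config.off_threshold:
            last = i
        elif (i - last) / sample_rate >= config.session_gap_timeout:
            sessions.append((start, last))
            start = last = None
            if v >= config.on_threshold:
                start = last = i
    if start is not None:
        sessions.append((start, last))
    return [
        (s, e)
        for s, e in sessions
        if (e - s) / sample_rate >= config.min_session_duration
    ]
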