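from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stimtrack import (
    DetectorConfig,
    StimulationProfile,
    VoltageTrace,
    average_peak_voltage,
    detect_and_log,
    detect_sessions,
    generate_trace,
)
from stimtrack.errors import InvalidParameterError, NoCyclesError
from stimtrack.session_detect import _session_bounds

from conftest import brute_force_sessions

T0 = datetime(2024, 1, 1, 9, 0)


def square_trace(bursts, sample_rate=10.0, amplitude=50.0):
    """Concatenate (active_seconds, silent_seconds) bursts into a trace."""
    parts = []
    for active, silent in bursts:
        parts.append(np.full(int(active * sample_rate), amplitude))
        parts.append(np.zeros(int(silent * sample_rate)))
    return VoltageTrace(T0, sample_rate, np.concatenate(parts))


class TestDetectSessions:
    def test_all_zero_trace_has_no_sessions(self, detector):
        trace = VoltageTrace(T0, 10.0, np.zeros(5000))
        assert detect_sessions(trace, detector) == []

    def test_ten_cycle_trace_is_one_session_matching_oracle(
        self, square_profile, detector
    ):
        trace = generate_trace(square_profile, 200.0, pre_silence=5.0, seed=0)
        sessions = detect_sessions(trace, detector)
        oracle = brute_force_sessions(trace.samples, trace.sample_rate, detector)
        assert len(sessions) == 1
        assert len(oracle) == 1
        start_idx, end_idx = oracle[0]
        assert sessions[0].start_time == trace.time_at(start_idx)
        assert sessions[0].end_time == trace.time_at(end_idx)
        # spans all 10 cycles: 9 full cycles plus the final contraction
        assert sessions[0].duration_seconds == pytest.approx(189.99)

    def test_burst_separation_splits_on_gap_timeout(self, detector):
        # silence longer than the 120 s timeout: two sessions
        far = square_trace([(100, 150), (100, 10)])
        assert len(detect_sessions(far, detector)) == 2
        # silence shorter than the timeout (but a real rest): one session
        near = square_trace([(100, 60), (100, 10)])
        assert len(detect_sessions(near, detector)) == 1
        for trace in (far, near):
            got = [
                (trace.index_at(s.start_time), trace.index_at(s.end_time))
                for s in detect_sessions(trace, detector)
            ]
            assert got == brute_force_sessions(
                trace.samples, trace.sample_rate, detector
            )

    def test_sub_threshold_trace_yields_nothing(self, detector):
        profile = StimulationProfile(amplitude=8.0, ramp_time=0.0)  # < on_threshold
        trace = generate_trace(profile, 200.0, seed=0)
        assert detect_and_log(trace, detector) == []

    def test_short_blips_are_discarded(self, detector):
        # 30 s of activity < min_session_duration of 60 s
        trace = square_trace([(30, 200)])
        assert detect_sessions(trace, detector) == []

    def test_detect_and_log_is_idempotent(self, square_profile, detector):
        trace = generate_trace(square_profile, 200.0, seed=0)
        assert detect_and_log(trace, detector) == detect_and_log(trace, detector)

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidParameterError):
            DetectorConfig(on_threshold=5.0, off_threshold=10.0)
        with pytest.raises(InvalidParameterError):
            DetectorConfig(session_gap_timeout=0.0)


class TestAveragePeakVoltage:
    def test_constant_amplitude_session(self, square_profile, detector):
        trace = generate_trace(square_profile, 200.0, seed=0)
        [session] = detect_sessions(trace, detector)
        assert session.avg_peak_voltage == 50.0

    def test_two_cycles_with_different_plateaus_average(self, detector):
        fs = 10.0
        samples = np.concatenate(
            [
                np.full(100, 40.0), np.zeros(100),
                np.full(100, 60.0), np.zeros(100),
            ]
        )
        trace = VoltageTrace(T0, fs, samples)
        value = average_peak_voltage(
            trace, T0, T0 + timedelta(seconds=39.9), detector
        )
        # brute force: per-cycle maxima are 40 and 60
        assert value == 50.0

    def test_ramped_cycles_peak_at_plateau(self, detector):
        profile = StimulationProfile(
            contraction_duration=10, relaxation_duration=10, amplitude=37.0,
            ramp_time=2.0, baseline_noise_sd=0.0, sample_rate=100,
        )
        trace = generate_trace(profile, 100.0, seed=0)
        [session] = detect_sessions(trace, detector)
        assert session.avg_peak_voltage == 37.0

    def test_window_without_cycles_raises(self, detector):
        trace = square_trace([(100, 300)])
        with pytest.raises(NoCyclesError):
            average_peak_voltage(
                trace,
                T0 + timedelta(seconds=150),
                T0 + timedelta(seconds=250),
                detector,
            )


def random_trace(rng: np.random.Generator) -> VoltageTrace:
    """Random bursts, amplitudes and gaps for the oracle-equivalence check."""
    parts = [np.zeros(rng.integers(0, 50))]
    for _ in range(rng.integers(1, 5)):
        amplitude = rng.uniform(3.0, 60.0)
        parts.append(np.full(rng.integers(5, 400), amplitude))
        parts.append(np.zeros(rng.integers(1, 400)))
    return VoltageTrace(T0, 10.0, np.concatenate(parts))


class TestOracleEquivalence:
    def test_detector_matches_brute_force_on_random_traces(self, detector):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            trace = random_trace(rng)
            expected = brute_force_sessions(
                trace.samples, trace.sample_rate, detector
            )
            got = _session_bounds(trace.samples, trace.sample_rate, detector)
            assert got == expected

    @given(seed=st.integers(0, 10_000))
    def test_raising_on_threshold_never_adds_sessions(self, seed):
        rng = np.random.default_rng(seed)
        trace = random_trace(rng)
        base = DetectorConfig(
            on_threshold=10.0, off_threshold=5.0,
            session_gap_timeout=20.0, min_session_duration=0.0,
        )
        counts = []
        for on in (10.0, 20.0, 30.0, 45.0):
            config = DetectorConfig(
                on_threshold=on, off_threshold=base.off_threshold,
                session_gap_timeout=base.session_gap_timeout,
                min_session_duration=base.min_session_duration,
            )
            counts.append(len(_session_bounds(trace.samples, 10.0, config)))
        assert counts == sorted(counts, reverse=True)

    @given(seed=st.integers(0, 10_000))
    def test_reported_sessions_respect_min_duration_and_peak_bound(self, seed):
        rng = np.random.default_rng(seed)
        trace = random_trace(rng)
        config = DetectorConfig(
            on_threshold=10.0, off_threshold=5.0,
            session_gap_timeout=20.0, min_session_duration=15.0,
        )
        for session in detect_sessions(trace, config):
            assert session.duration_seconds >= config.min_session_duration
            i0 = trace.index_at(session.start_time)
            i1 = trace.index_at(session.end_time)
            assert session.avg_peak_voltage <= trace.samples[i0 : i1 + 1].max()
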