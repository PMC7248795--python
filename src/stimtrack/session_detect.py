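"""Threshold state-machine session detection and per-session intensity.

The monitoring firmware watches the rectified stimulation voltage and
segments it into therapy sessions: a session opens at the first sample at
or above ``on_threshold`` and closes at the last sample at or above
``off_threshold`` before a continuous sub-threshold gap of at least
``session_gap_timeout`` seconds (or the end of the trace).  Two thresholds
(hysteresis) prevent chatter at cycle edges.  The per-session intensity
statistic is the average peak voltage: the mean over contraction cycles of
each cycle's maximum, where a contraction cycle is a maximal run of samples
at or above ``off_threshold`` — the same level the detector uses, so the
detector and the statistic agree on what counts as a contraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, NoCyclesError
from .waveform import VoltageTrace

__all__ = [
    "DetectorConfig",
    "SessionRecord",
    "detect_sessions",
    "average_peak_voltage",
    "detect_and_log",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Detector thresholds and timing.

    ``session_gap_timeout`` (default 120 s) must exceed any plausible
    relaxation phase so intra-session rests never split a session;
    ``min_session_duration`` (default 60 s) suppresses accidental power-on
    blips.
    """

    on_threshold: float = 10.0
    off_threshold: float = 5.0
    session_gap_timeout: float = 120.0
    min_session_duration: float = 60.0

    def __post_init__(self) -> None:
        if self.on_threshold <= 0:
            raise InvalidParameterError("on_threshold must be positive")
        if self.off_threshold < 0 or self.off_threshold > self.on_threshold:
            raise InvalidParameterError(
                "off_threshold must satisfy 0 <= off_threshold <= on_threshold"
            )
        if self.session_gap_timeout <= 0:
            raise InvalidParameterError("session_gap_timeout must be positive")
        if self.min_session_duration < 0:
            raise InvalidParameterError("min_session_duration must be >= 0")


@dataclass(frozen=True)
class SessionRecord:
    """One detected therapy session."""

    start_time: datetime
    end_time: datetime
    avg_peak_voltage: float

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise InvalidInputError("end_time must be after start_time")
        if self.avg_peak_voltage < 0:
            raise InvalidInputError("avg_peak_voltage must be non-negative")

    @property
    def duration_seconds(self) -> float:
        return (self.end_time - self.start_time).total_seconds()

    def to_dict(self) -> dict:
        return {
            "start_time": self.start_time.isoformat(),
            "end_time": self.end_time.isoformat(),
            "avg_peak_voltage": self.avg_peak_voltage,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "SessionRecord":
        return cls(
            datetime.fromisoformat(obj["start_time"]),
            datetime.fromisoformat(obj["end_time"]),
            float(obj["avg_peak_voltage"]),
        )


def _active_runs(samples: np.ndarray, level: float) -> list[tuple[int, int]]:
    """Maximal runs of samples >= level, as inclusive (first, last) indices."""
    above = samples >= level
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(samples) - 1)
    return list(zip(starts, ends))


def _session_bounds(
    samples: np.ndarray, sample_rate: float, config: DetectorConfig
) -> list[tuple[int, int]]:
    """Inclusive (start, end) sample indices of detected sessions."""
    runs = _active_runs(samples, config.off_threshold)
    if not runs:
        return []
    gap_samples = config.session_gap_timeout * sample_rate

    # Merge supra-off runs separated by sub-threshold gaps shorter than the
    # timeout; each merged group is one candidate session.
    groups: list[list[tuple[int, int]]] = [[runs[0]]]
    for run in runs[1:]:
        gap = run[0] - groups[-1][-1][1] - 1
        if gap >= gap_samples:
            groups.append([run])
        else:
            groups[-1].append(run)

    bounds: list[tuple[int, int]] = []
    for group in groups:
        lo, hi = group[0][0], group[-1][1]
        segment = samples[lo : hi + 1]
        over_on = np.flatnonzero(segment >= config.on_threshold)
        if over_on.size == 0:
            continue  # never armed: no sample reached the on threshold
        start = lo + int(over_on[0])
        if (hi - start) / sample_rate < config.min_session_duration:
            continue
        bounds.append((start, hi))
    return bounds


def average_peak_voltage(
    trace: VoltageTrace,
    start: datetime,
    end: datetime,
    config: DetectorConfig,
) -> float:
    """Mean over contraction cycles of each cycle's maximum voltage.

    The window [start, end] must lie within the trace and contain at least
    one contraction cycle (run of samples >= ``off_threshold``).
    """
    i0 = trace.index_at(start)
    i1 = trace.index_at(end)
    if i0 < 0 or i1 >= len(trace) or i1 < i0:
        raise InvalidInputError("window outside trace bounds")
    window = trace.samples[i0 : i1 + 1]
    runs = _active_runs(window, config.off_threshold)
    if not runs:
        raise NoCyclesError("window contains no supra-threshold cycle")
    peaks = [float(window[a : b + 1].max()) for a, b in runs]
    return float(np.mean(peaks))


def detect_sessions(
    trace: VoltageTrace, config: DetectorConfig
) -> list[SessionRecord]:
    """Segment a trace into non-overlapping, time-ordered session records."""
    if len(trace) == 0:  # VoltageTrace forbids this, but guard duck-typed input
        raise InvalidInputError("empty trace")
    records = []
    for start_idx, end_idx in _session_bounds(
        trace.samples, trace.sample_rate, config
    ):
        start = trace.time_at(start_idx)
        end = trace.time_at(end_idx)
        records.append(
            SessionRecord(start, end, average_peak_voltage(trace, start, end, config))
        )
    return records


def detect_and_log(trace: VoltageTrace, config: DetectorConfig) -> list[SessionRecord]:
    """Detect sessions and return records ready for the telemetry codec.

    Idempotent: running it twice on the same trace yields equal records.
    """
    return detect_sessions(trace, config)
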