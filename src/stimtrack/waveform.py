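"""Synthetic NMES output-voltage traces.

During a therapy session an NMES device emits alternating phases of high
voltage (muscle contraction) and near-zero voltage (relaxation).  The
monitoring hardware sees this envelope through a rectifier, so the signal
is non-negative.  This module generates such traces: each contraction is a
trapezoid (linear ramp to the plateau amplitude, plateau for the remainder
of the contraction phase, instantaneous release), repeated for as many full
cycles as fit into the requested session duration, flanked by silence, with
optional additive Gaussian noise clipped at zero.

The generator is deliberately pure: the same profile and seed always yield
bit-identical samples.  Clock drift and other device pathologies are
injected downstream by the cohort simulator, never here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["StimulationProfile", "VoltageTrace", "generate_trace"]

#: Default absolute start used when a caller does not care about wall time.
DEFAULT_START = datetime(2024, 1, 1, 9, 0, 0)


@dataclass(frozen=True)
class StimulationProfile:
    """Timing and amplitude of the contraction/relaxation duty cycle.

    Parameters
    ----------
    contraction_duration
        Length of the high-voltage phase, seconds (> 0).
    relaxation_duration
        Length of the near-zero phase, seconds (> 0).
    amplitude
        Plateau voltage in arbitrary device units (>= 0).
    ramp_time
        Linear rise time to the plateau within each contraction, seconds;
        must be shorter than the contraction itself.
    baseline_noise_sd
        Standard deviation of zero-mean Gaussian noise added to every
        sample; the sum is clipped at 0 (rectified output is non-negative).
    sample_rate
        Sampling frequency in Hz (> 0).
    """

    contraction_duration: float = 10.0
    relaxation_duration: float = 10.0
    amplitude: float = 50.0
    ramp_time: float = 2.0
    baseline_noise_sd: float = 0.0
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.contraction_duration <= 0 or self.relaxation_duration <= 0:
            raise InvalidParameterError("phase durations must be positive")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")
        if self.amplitude < 0:
            raise InvalidParameterError("amplitude must be non-negative")
        if self.ramp_time < 0 or self.ramp_time >= self.contraction_duration:
            raise InvalidParameterError(
                "ramp_time must satisfy 0 <= ramp_time < contraction_duration"
            )
        if self.baseline_noise_sd < 0:
            raise InvalidParameterError("baseline_noise_sd must be non-negative")

    @property
    def cycle_duration(self) -> float:
        """One full contraction + relaxation cycle, seconds."""
        return self.contraction_duration + self.relaxation_duration

    def with_amplitude(self, amplitude: float) -> "StimulationProfile":
        return replace(self, amplitude=amplitude)


@dataclass
class VoltageTrace:
    """A uniformly sampled voltage signal with an absolute start time."""

    start_timestamp: datetime
    sample_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise InvalidInputError("trace must contain at least one sample")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Trace span in seconds (first to one-past-last sample)."""
        return len(self) / self.sample_rate

    def time_at(self, index: int) -> datetime:
        """Absolute timestamp of sample ``index``."""
        return self.start_timestamp + timedelta(seconds=index / self.sample_rate)

    def index_at(self, when: datetime) -> int:
        """Nearest sample index for an absolute timestamp."""
        offset = (when - self.start_timestamp).total_seconds()
        return int(round(offset * self.sample_rate))

    # -- serialisation -----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write as two columns: ISO-8601 timestamp, voltage."""
        times = [self.time_at(i).isoformat() for i in range(len(self))]
        pd.DataFrame({"timestamp": times, "voltage": self.samples}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "VoltageTrace":
        frame = pd.read_csv(path)
        frame["timestamp"] = pd.to_datetime(frame["timestamp"], format="ISO8601")
        if len(frame) < 2:
            raise InvalidInputError("trace CSV needs at least two samples")
        deltas = frame["timestamp"].diff().dropna().dt.total_seconds()
        rate = 1.0 / float(deltas.median())
        start = frame["timestamp"].iloc[0].to_pydatetime()
        return cls(start, rate, frame["voltage"].to_numpy(dtype=float))

    def to_json(self, path: str | Path) -> None:
        obj = {
            "start_timestamp": self.start_timestamp.isoformat(),
            "sample_rate": self.sample_rate,
            "samples": self.samples.tolist(),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "VoltageTrace":
        obj = json.loads(Path(path).read_text())
        return cls(
            datetime.fromisoformat(obj["start_timestamp"]),
            float(obj["sample_rate"]),
            np.asarray(obj["samples"], dtype=float),
        )


def generate_trace(
    profile: StimulationProfile,
    session_duration: float,
    pre_silence: float = 0.0,
    post_silence: float = 0.0,
    seed: int = 0,
    start_timestamp: datetime = DEFAULT_START,
) -> VoltageTrace:
    """Generate a synthetic session trace.

    The active region contains ``floor(session_duration / cycle_duration)``
    full contraction/relaxation cycles; any fractional remainder is left
    silent so that cycle counting is exact.  Noise (if any) covers the whole
    trace, silence included, and is clipped at zero.

    Parameters
    ----------
    profile
        Duty-cycle shape and noise level.
    session_duration
        Nominal active span in seconds; must fit at least one full cycle.
    pre_silence, post_silence
        Silent padding before/after the active region, seconds.
    seed
        Seed for the noise generator; identical seeds give bit-identical
        traces.
    start_timestamp
        Absolute time of the first sample.
    """
    if session_duration <= 0:
        raise InvalidParameterError("session_duration must be positive")
    if pre_silence < 0 or post_silence < 0:
        raise InvalidParameterError("silence durations must be non-negative")
    cycle = profile.cycle_duration
    if session_duration < cycle:
        raise InvalidParameterError(
            "session_duration must cover at least one full cycle"
        )

    fs = profile.sample_rate
    n = int(round((pre_silence + session_duration + post_silence) * fs))
    t = np.arange(n) / fs
    rel = t - pre_silence
    n_cycles = int(math.floor(session_duration / cycle))
    active = (rel >= 0) & (rel < n_cycles * cycle)
    phase = np.mod(rel, cycle)

    volts = np.zeros(n)
    contracting = active & (phase < profile.contraction_duration)
    if profile.ramp_time > 0:
        with np.errstate(over="ignore"):  # denormal ramp times clip to 1
            rise = np.clip(phase / profile.ramp_time, 0.0, 1.0)
    else:
        rise = np.ones_like(phase)
    volts[contracting] = profile.amplitude * rise[contracting]

    if profile.baseline_noise_sd > 0:
        rng = np.random.default_rng(seed)
        volts = np.clip(
            volts + rng.normal(0.0, profile.baseline_noise_sd, size=n), 0.0, None
        )
    return VoltageTrace(start_timestamp, fs, volts)
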