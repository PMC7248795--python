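"""Kit-wide configuration: detector, prescription, pools, cohort profiles.

A single YAML file can override any part; omitted sections fall back to
defaults that mirror the pilot-scale study conditions (seven patients,
two-week enrolment, five sessions per week, one representative of each
observed failure mode).  Cross-references are validated at load time —
in particular, every adherence-engine event type must map to a nonempty
message pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .adherence import EventType, Prescription
from .errors import ConfigurationError
from .notifications import MessagePool, DEFAULT_POOLS
from .session_detect import DetectorConfig
from .simulate import BehaviorProfile, FailureMode
from .waveform import StimulationProfile

__all__ = ["KitConfig", "load_kit_config", "default_cohort_profiles"]


def default_cohort_profiles() -> list[BehaviorProfile]:
    """Seven pilot-like patients: four typical, one of each failure mode.

    The cohort mirrors the formative-pilot composition: most patients use
    and sync the device as intended, one never syncs, one device counter
    runs wild, one patient abandons the device when batteries die, and one
    device clock drifts.
    """
    return [
        BehaviorProfile(),
        BehaviorProfile(),
        BehaviorProfile(),
        BehaviorProfile(failure_mode=FailureMode.NEVER_SYNC),
        BehaviorProfile(failure_mode=FailureMode.SPURIOUS_DEVICE_COUNT),
        BehaviorProfile(failure_mode=FailureMode.BATTERY_ABANDON),
        BehaviorProfile(failure_mode=FailureMode.CLOCK_DRIFT),
    ]


@dataclass
class KitConfig:
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    prescription: Prescription = field(default_factory=Prescription)
    stimulation: StimulationProfile = field(default_factory=StimulationProfile)
    pools: dict[EventType, MessagePool] = field(
        default_factory=lambda: dict(DEFAULT_POOLS)
    )
    profiles: list[BehaviorProfile] = field(default_factory=default_cohort_profiles)
    weeks: int = 2
    seed: int = 17

    def __post_init__(self) -> None:
        missing = [et.value for et in EventType if et not in self.pools]
        if missing:
            raise ConfigurationError(f"no message pool for event types: {missing}")
        if self.weeks < 1:
            raise ConfigurationError("weeks must be >= 1")


def _build(cls, raw: dict, **extra):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**{**raw, **extra})


def load_kit_config(path: str | Path | None = None) -> KitConfig:
    """Load a YAML configuration, falling back to defaults per section."""
    if path is None:
        return KitConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}

    kwargs: dict = {}
    if "detector" in raw:
        kwargs["detector"] = _build(DetectorConfig, raw["detector"])
    if "prescription" in raw:
        kwargs["prescription"] = _build(Prescription, raw["prescription"])
    if "stimulation" in raw:
        kwargs["stimulation"] = _build(StimulationProfile, raw["stimulation"])
    if "pools" in raw:
        pools = {}
        for key, messages in raw["pools"].items():
            event_type = EventType(key)
            pools[event_type] = MessagePool(event_type, tuple(messages))
        # Unspecified event types keep their default pools.
        kwargs["pools"] = {**DEFAULT_POOLS, **pools}
    if "cohort" in raw:
        cohort = dict(raw["cohort"])
        if "weeks" in cohort:
            kwargs["weeks"] = int(cohort.pop("weeks"))
        profiles = []
        for entry in cohort.pop("patients", []):
            entry = dict(entry)
            if "failure_mode" in entry:
                entry["failure_mode"] = FailureMode(entry["failure_mode"])
            profiles.append(_build(BehaviorProfile, entry))
        if profiles:
            kwargs["profiles"] = profiles
        if cohort:
            raise ConfigurationError(f"unknown cohort keys: {sorted(cohort)}")
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return KitConfig(**kwargs)
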