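"""Synthetic patient behaviour: sessions, self-report bias, failure modes.

No stimulation-device dataset accompanies the monitoring system, so the
whole downstream pipeline is exercised against simulated patients.  The
simulator emulates the pilot-scale study conditions: patients prescribed
five one-hour sessions per 7-day week, enrolled for one to two weeks,
completing most scheduled sessions, occasionally over-reporting use on
paper logs (the covert device counter showed roughly 12–15% excess
self-report in the field), and exhibiting the observed failure modes:

``never_sync``
    The patient completes sessions but never uploads them.
``spurious_device_count``
    The device's internal use counter inflates wildly (values like 34 or
    135 sessions over a two-week enrolment) while actual behaviour is
    normal.
``battery_abandon``
    The patient stops doing sessions after the batteries run out.
``clock_drift``
    The device real-time clock runs fast; synced records carry drifted
    timestamps until the sync step re-stamps them.

Over-reporting is modelled per completed session: with probability
``overreport_prob`` a completed session spawns one phantom self-report
entry, so the expected self-report/device ratio is exactly
1 + overreport_prob and the configured rate is recoverable from large
cohorts as a plain binomial proportion.

Per-patient random streams are derived from the cohort seed and the
patient index via :class:`numpy.random.SeedSequence`, so appending a
patient to a cohort never perturbs earlier patients' timelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .session_detect import SessionRecord
from .waveform import StimulationProfile, VoltageTrace, generate_trace

__all__ = [
    "FailureMode",
    "BehaviorProfile",
    "SimulatedPatient",
    "Cohort",
    "simulate_patient",
    "simulate_cohort",
    "render_session_traces",
]


class FailureMode(str, Enum):
    NONE = "none"
    NEVER_SYNC = "never_sync"
    SPURIOUS_DEVICE_COUNT = "spurious_device_count"
    BATTERY_ABANDON = "battery_abandon"
    CLOCK_DRIFT = "clock_drift"


@dataclass(frozen=True)
class BehaviorProfile:
    """Tunable patient behaviour.

    Defaults reflect a mostly adherent pilot-style patient: five scheduled
    days per week, 90% chance of completing each scheduled session, 12%
    over-report probability per completed session, and a 95% chance that a
    completed session is eventually synced (usually the same evening).
    Session intensity is drawn per session around 36 arbitrary device units
    with a wide spread (sd 13), matching the large day-to-day variability
    of stimulation tolerance after knee surgery.
    """

    weekly_target: int = 5
    completion_prob_per_scheduled_day: float = 0.9
    overreport_prob: float = 0.12
    sync_prob: float = 0.95
    sync_latency_mean_days: float = 0.3
    failure_mode: FailureMode = FailureMode.NONE
    session_minutes: int = 60
    intensity_mean: float = 36.0
    intensity_sd: float = 13.0
    #: Device clock gain, seconds per elapsed day (clock_drift mode only).
    drift_seconds_per_day: float = 3600.0
    #: Inflation factor range for spurious_device_count mode.
    spurious_inflation: tuple[float, float] = (4.0, 15.0)

    def __post_init__(self) -> None:
        for name in ("completion_prob_per_scheduled_day", "overreport_prob", "sync_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        if self.weekly_target < 0 or self.weekly_target > 7:
            raise ConfigurationError("weekly_target must lie in [0, 7]")
        if self.session_minutes <= 0:
            raise ConfigurationError("session_minutes must be positive")


@dataclass
class SimulatedPatient:
    """Ground truth and observables for one simulated patient."""

    patient_id: str
    start_date: date
    profile: BehaviorProfile
    #: Sessions the patient actually performed (wall-clock timestamps).
    true_sessions: list[SessionRecord] = field(default_factory=list)
    #: Dates the patient wrote on the paper log (includes phantoms).
    self_report_dates: list[date] = field(default_factory=list)
    #: The device's internal use counter (inflated under spurious mode).
    device_log_count: int = 0
    #: Records as they leave the device (drifted timestamps under drift).
    synced_sessions: list[SessionRecord] = field(default_factory=list)
    #: When each synced record was uploaded, parallel to synced_sessions.
    sync_times: list[datetime] = field(default_factory=list)
    #: Indices into true_sessions of the sessions that were synced.
    synced_indices: list[int] = field(default_factory=list)

    @property
    def elapsed_days(self) -> int:
        if not self.true_sessions and not self.self_report_dates:
            return 7
        last = self.start_date
        for record in self.true_sessions:
            last = max(last, record.start_time.date())
        for day in self.self_report_dates:
            last = max(last, day)
        return (last - self.start_date).days + 1

    def clock_offset_at(self, when: datetime) -> timedelta:
        """Device clock error accumulated by wall-clock time ``when``."""
        if self.profile.failure_mode is not FailureMode.CLOCK_DRIFT:
            return timedelta(0)
        days = (when - datetime.combine(self.start_date, time())).total_seconds() / 86400.0
        return timedelta(seconds=self.profile.drift_seconds_per_day * max(days, 0.0))

    def device_stamp_offset(self, record: SessionRecord) -> timedelta:
        """Clock error the device applied when stamping ``record``."""
        if self.profile.failure_mode is not FailureMode.CLOCK_DRIFT:
            return timedelta(0)
        day_offset = (record.start_time.date() - self.start_date).days
        return timedelta(seconds=self.profile.drift_seconds_per_day * day_offset)


def _patient_rng(cohort_seed: int, patient_index: int) -> np.random.Generator:
    """Independent per-patient stream, stable under cohort growth."""
    return np.random.default_rng(np.random.SeedSequence([cohort_seed, patient_index]))


def simulate_patient(
    profile: BehaviorProfile,
    weeks: int,
    seed: int,
    patient_id: str = "SIM-0",
    start_date: date = date(2024, 1, 1),
    patient_index: int = 0,
) -> SimulatedPatient:
    """Simulate one patient's behaviour over ``weeks`` 7-day weeks."""
    if weeks < 1:
        raise ConfigurationError("weeks must be >= 1")
    rng = _patient_rng(seed, patient_index)
    patient = SimulatedPatient(patient_id, start_date, profile)
    mode = profile.failure_mode
    total_days = weeks * 7

    abandon_after: int | None = None
    if mode is FailureMode.BATTERY_ABANDON:
        # Batteries die partway through the enrolment; no sessions after.
        abandon_after = int(rng.integers(2, max(total_days - 1, 3)))

    drift_per_day = (
        profile.drift_seconds_per_day if mode is FailureMode.CLOCK_DRIFT else 0.0
    )

    for week in range(weeks):
        scheduled = np.sort(
            rng.choice(7, size=profile.weekly_target, replace=False)
        )
        for day_in_week in scheduled:
            day_offset = week * 7 + int(day_in_week)
            if abandon_after is not None and day_offset >= abandon_after:
                continue
            if rng.random() >= profile.completion_prob_per_scheduled_day:
                continue
            # Session start uniform within the waking window 08:00-21:00.
            start_minute = int(rng.integers(8 * 60, 21 * 60))
            start = datetime.combine(
                start_date + timedelta(days=day_offset), time()
            ) + timedelta(minutes=start_minute)
            end = start + timedelta(minutes=profile.session_minutes)
            # Floor at the minimum effective amplitude: stimulation much
            # weaker than this triggers no visible contraction envelope.
            intensity = float(
                np.clip(rng.normal(profile.intensity_mean, profile.intensity_sd), 15.0, None)
            )
            record = SessionRecord(start, end, intensity)
            patient.true_sessions.append(record)
            patient.self_report_dates.append(start.date())
            if rng.random() < profile.overreport_prob:
                # Phantom paper-log entry with no matching device activity.
                patient.self_report_dates.append(start.date())

            if mode is FailureMode.NEVER_SYNC:
                continue
            if rng.random() < profile.sync_prob:
                latency_days = int(rng.poisson(profile.sync_latency_mean_days))
                synced_at = end + timedelta(days=latency_days, minutes=30)
                offset = timedelta(seconds=drift_per_day * day_offset)
                device_record = SessionRecord(
                    start + offset, end + offset, intensity
                )
                patient.synced_sessions.append(device_record)
                patient.sync_times.append(synced_at)
                patient.synced_indices.append(len(patient.true_sessions) - 1)

    patient.device_log_count = len(patient.true_sessions)
    if mode is FailureMode.SPURIOUS_DEVICE_COUNT:
        lo, hi = profile.spurious_inflation
        factor = float(rng.uniform(lo, hi))
        patient.device_log_count = max(
            int(round(len(patient.true_sessions) * factor)),
            len(patient.true_sessions) + 1,
        )
    return patient


@dataclass
class Cohort:
    """A simulated cohort plus its aggregate session ledger."""

    patients: list[SimulatedPatient]
    weeks: int

    def ledger(self) -> pd.DataFrame:
        """Per-patient counts in the reporting module's ledger schema."""
        rows = []
        for patient in self.patients:
            flags = []
            if patient.profile.failure_mode is FailureMode.NEVER_SYNC:
                flags.append("never_sync")
            if patient.profile.failure_mode is FailureMode.SPURIOUS_DEVICE_COUNT:
                flags.append("spurious_device")
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "self_reported": len(patient.self_report_dates),
                    "system_recorded": len(patient.synced_sessions),
                    "device_logged": patient.device_log_count,
                    "elapsed_days": self.weeks * 7,
                    "notifications_expected": np.nan,
                    "notifications_received": np.nan,
                    "flags": ";".join(flags),
                }
            )
        return pd.DataFrame(rows)


def simulate_cohort(
    profiles: list[BehaviorProfile],
    weeks: int,
    seed: int,
    start_date: date = date(2024, 1, 1),
) -> Cohort:
    """Simulate one patient per profile with independent random streams."""
    if not profiles:
        raise ConfigurationError("cohort needs at least one profile")
    patients = [
        simulate_patient(
            profile,
            weeks,
            seed,
            patient_id=f"SIM-{index}",
            start_date=start_date,
            patient_index=index,
        )
        for index, profile in enumerate(profiles)
    ]
    return Cohort(patients, weeks)


def render_session_traces(
    patient: SimulatedPatient,
    stim_profile: StimulationProfile,
    pre_silence: float = 5.0,
    post_silence: float = 5.0,
) -> list[VoltageTrace]:
    """One voltage trace per true session, at the session's own intensity.

    Under noise-free settings the detector applied to these traces
    recovers the patient's session count exactly.
    """
    traces = []
    for index, record in enumerate(patient.true_sessions):
        profile = stim_profile.with_amplitude(record.avg_peak_voltage)
        traces.append(
            generate_trace(
                profile,
                session_duration=record.duration_seconds,
                pre_silence=pre_silence,
                post_silence=post_silence,
                seed=index,
                start_timestamp=record.start_time
                - timedelta(seconds=pre_silence),
            )
        )
    return traces
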