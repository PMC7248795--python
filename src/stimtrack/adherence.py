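"""Calendar-anchored weekly adherence classification and scheduled checks.

The prescription is five one-hour stimulation sessions per 7-day week,
with weeks anchored to each patient's start date (day 1 = start date).
Adherence is assessed from *synced* sessions — the server can only see
what was uploaded — and is checked twice per week:

* day 3: if the week opened with three consecutive days without a synced
  session, a midweek reminder is emitted;
* day 7: the week is classified as compliant (> 4 sessions), almost
  compliant (3–4) or noncompliant (< 3); a noncompliant week additionally
  raises a clinician alert.

Sessions are attributed to weeks by their start time, in whole local
calendar days; a session counts regardless of its duration or intensity
(the one-hour prescription is reported, not enforced).  Checks are
point-in-time: the day-3 reminder fires even if the patient later
completes the full week.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from enum import Enum

from .errors import InvalidInputError, InvalidParameterError
from .session_detect import SessionRecord

__all__ = [
    "AdherenceStatus",
    "EventType",
    "Prescription",
    "PatientTimeline",
    "AdherenceCheckResult",
    "classify_week",
    "week_and_day",
    "run_check",
    "on_session_synced",
    "scheduled_checks",
]


class AdherenceStatus(str, Enum):
    COMPLIANT = "compliant"
    ALMOST_COMPLIANT = "almost_compliant"
    NONCOMPLIANT = "noncompliant"


class EventType(str, Enum):
    """Notification-triggering events emitted by the adherence engine."""

    AFTER_SESSION = "after_session"
    WEEKLY_COMPLIANT = "weekly_compliant"
    WEEKLY_ALMOST = "weekly_almost"
    WEEKLY_NONCOMPLIANT = "weekly_noncompliant"
    MIDWEEK_REMINDER = "midweek_reminder"


_WEEKLY_EVENT = {
    AdherenceStatus.COMPLIANT: EventType.WEEKLY_COMPLIANT,
    AdherenceStatus.ALMOST_COMPLIANT: EventType.WEEKLY_ALMOST,
    AdherenceStatus.NONCOMPLIANT: EventType.WEEKLY_NONCOMPLIANT,
}


@dataclass(frozen=True)
class Prescription:
    """Weekly session prescription. The week length is fixed at 7 days."""

    sessions_per_week: int = 5
    session_duration_minutes: int = 60
    week_length_days: int = 7

    def __post_init__(self) -> None:
        if self.sessions_per_week < 1:
            raise InvalidParameterError("sessions_per_week must be >= 1")
        if self.week_length_days != 7:
            raise InvalidParameterError("week_length_days is fixed at 7")


def classify_week(sessions: int) -> AdherenceStatus:
    """Classify a week from its synced-session count.

    > 4 sessions: compliant; 3–4: almost compliant; < 3: noncompliant.
    Total and monotone: more sessions never worsen the status.
    """
    if sessions < 0:
        raise InvalidInputError("session count must be non-negative")
    if sessions > 4:
        return AdherenceStatus.COMPLIANT
    if sessions >= 3:
        return AdherenceStatus.ALMOST_COMPLIANT
    return AdherenceStatus.NONCOMPLIANT


def _as_date(value: date | datetime) -> date:
    return value.date() if isinstance(value, datetime) else value


def week_and_day(start_date: date | datetime, event_date: date | datetime) -> tuple[int, int]:
    """Map an event date to (week_number, day_index), both 1-based.

    Weeks are consecutive 7-day blocks from the patient's start date, so
    the start date itself is week 1, day 1.
    """
    start, event = _as_date(start_date), _as_date(event_date)
    elapsed = (event - start).days
    if elapsed < 0:
        raise InvalidInputError("event date precedes start date")
    return 1 + elapsed // 7, 1 + elapsed % 7


@dataclass
class PatientTimeline:
    """A patient's start date plus synced sessions and self-report dates."""

    patient_id: str
    start_date: date
    sessions: dict[datetime, SessionRecord] = field(default_factory=dict)
    self_report_dates: list[date] = field(default_factory=list)

    def add_session(self, record: SessionRecord) -> bool:
        """Add a synced session; returns False for a duplicate start time."""
        if record.start_time in self.sessions:
            return False
        self.sessions[record.start_time] = record
        return True

    def sessions_in_days(self, week_number: int, first_day: int, last_day: int) -> int:
        """Count synced sessions whose start falls on the given days of a week."""
        count = 0
        for record in self.sessions.values():
            week, day = week_and_day(self.start_date, record.start_time)
            if week == week_number and first_day <= day <= last_day:
                count += 1
        return count


@dataclass(frozen=True)
class AdherenceCheckResult:
    """Outcome of one scheduled check (day 3 or day 7 of a patient week)."""

    patient_id: str
    week_number: int
    check_day: int
    status: AdherenceStatus | None  # None for day-3 checks
    reminder: bool
    clinician_alert: bool

    def events(self) -> list[EventType]:
        """Notification events this check result triggers."""
        if self.check_day == 3:
            return [EventType.MIDWEEK_REMINDER] if self.reminder else []
        assert self.status is not None
        return [_WEEKLY_EVENT[self.status]]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "week": self.week_number,
            "check_day": self.check_day,
            "status": self.status.value if self.status else None,
            "reminder": self.reminder,
            "alert": self.clinician_alert,
        }


def run_check(
    timeline: PatientTimeline, week_number: int, check_day: int
) -> AdherenceCheckResult:
    """Run the day-3 or day-7 scheduled check for one patient week."""
    if check_day not in (3, 7):
        raise InvalidInputError("checks run only on days 3 and 7")
    if week_number < 1:
        raise InvalidInputError("week_number must be >= 1")
    if check_day == 3:
        reminder = timeline.sessions_in_days(week_number, 1, 3) == 0
        return AdherenceCheckResult(
            timeline.patient_id, week_number, 3, None, reminder, False
        )
    status = classify_week(timeline.sessions_in_days(week_number, 1, 7))
    return AdherenceCheckResult(
        timeline.patient_id,
        week_number,
        7,
        status,
        False,
        status is AdherenceStatus.NONCOMPLIANT,
    )


def on_session_synced(
    timeline: PatientTimeline, record: SessionRecord
) -> EventType | None:
    """Register a newly synced session; emit one after-session event.

    Duplicate syncs (same start time) produce no event, so the number of
    after-session events always equals the number of distinct sessions.
    """
    if record.start_time.date() < timeline.start_date:
        raise InvalidInputError("session precedes patient start date")
    return EventType.AFTER_SESSION if timeline.add_session(record) else None


def scheduled_checks(
    timeline: PatientTimeline, weeks: int
) -> list[AdherenceCheckResult]:
    """Run both scheduled checks for each of the first ``weeks`` weeks."""
    results = []
    for week in range(1, weeks + 1):
        results.append(run_check(timeline, week, 3))
        results.append(run_check(timeline, week, 7))
    return results
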