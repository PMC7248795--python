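"""Functional-correctness arithmetic and clinician-facing summaries.

The pilot evaluation of the monitoring system compared three session
counts per patient — paper self-report, system-recorded (synced) sessions,
and the stimulation device's own covert use counter — plus notification
delivery logs.  This module computes the capture and bias percentages from
such a ledger:

* system capture vs. self-report, over all patients and excluding the
  patient who never synced;
* system capture vs. the device counter, excluding patients whose counter
  was spuriously inflated (flagged when the count exceeds
  ``elapsed_days x max_sessions_per_day``);
* the self-report over-reporting bias relative to the device counter;
* the fraction of expected push notifications actually received, over
  patients with complete notification logs.

All percentages are rounded to the nearest integer, half away from zero.
A transcription of the pilot's per-patient ledger ships with the package
(``data/pilot_ledger.csv``); two rows there are printed only as
two-patient aggregates and carry a synthetic even/forced split, noted in
the file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .adherence import AdherenceStatus, PatientTimeline, run_check
from .errors import InvalidInputError

__all__ = [
    "pilot_ledger",
    "load_ledger",
    "capture_fraction",
    "overreport_percent",
    "flag_spurious_device_counts",
    "CorrectnessSummary",
    "summarize",
    "clinician_report",
]

LEDGER_COLUMNS = [
    "patient_id",
    "self_reported",
    "system_recorded",
    "device_logged",
    "elapsed_days",
    "notifications_expected",
    "notifications_received",
    "flags",
]

_STATUS_ORDER = {
    AdherenceStatus.NONCOMPLIANT: 0,
    AdherenceStatus.ALMOST_COMPLIANT: 1,
    AdherenceStatus.COMPLIANT: 2,
}


def load_ledger(path: str | Path) -> pd.DataFrame:
    """Read a session ledger CSV, normalising missing flag/count fields."""
    frame = pd.read_csv(path)
    missing = [c for c in LEDGER_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"ledger missing columns: {missing}")
    frame["flags"] = frame["flags"].fillna("")
    return frame


def pilot_ledger() -> pd.DataFrame:
    """The bundled per-patient pilot ledger."""
    with resources.as_file(
        resources.files("stimtrack.data").joinpath("pilot_ledger.csv")
    ) as path:
        return load_ledger(path)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def capture_fraction(recorded: int, comparator: int) -> int:
    """Integer percentage of comparator sessions captured by the system."""
    if comparator <= 0:
        raise InvalidInputError("comparator count must be positive")
    if recorded < 0:
        raise InvalidInputError("recorded count must be non-negative")
    return _round_half_away(100.0 * recorded / comparator)


def overreport_percent(self_reported: int, device_logged: int) -> int:
    """Integer percentage excess of self-report over the device counter."""
    if device_logged <= 0:
        raise InvalidInputError("device-logged count must be positive")
    return _round_half_away(100.0 * (self_reported - device_logged) / device_logged)


def flag_spurious_device_counts(
    ledger: pd.DataFrame, max_sessions_per_day: int = 2
) -> pd.DataFrame:
    """Flag rows whose device counter exceeds a plausibility cap.

    A counter above ``elapsed_days * max_sessions_per_day`` cannot reflect
    real behaviour at pilot time scales and is excluded from device-based
    comparisons.  Returns a copy with ``spurious_device`` added to flags.
    """
    out = ledger.copy()
    cap = out["elapsed_days"] * max_sessions_per_day
    spurious = out["device_logged"].fillna(-1) > cap

    def add_flag(flags: str) -> str:
        parts = [p for p in str(flags).split(";") if p]
        if "spurious_device" not in parts:
            parts.append("spurious_device")
        return ";".join(parts)

    out.loc[spurious, "flags"] = out.loc[spurious, "flags"].apply(add_flag)
    return out


def _has_flag(flags: str, name: str) -> bool:
    return name in str(flags).split(";")


@dataclass(frozen=True)
class CorrectnessSummary:
    """Aggregate functional-correctness percentages for a ledger."""

    capture_vs_self_report_pct: int | None
    capture_vs_self_report_excl_nonsync_pct: int | None
    capture_vs_device_pct: int | None
    overreport_pct: int | None
    notifications_received_pct: int | None
    excluded_patients: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "capture_vs_self_report_pct": self.capture_vs_self_report_pct,
            "capture_vs_self_report_excl_nonsync_pct": (
                self.capture_vs_self_report_excl_nonsync_pct
            ),
            "capture_vs_device_pct": self.capture_vs_device_pct,
            "overreport_pct": self.overreport_pct,
            "notifications_received_pct": self.notifications_received_pct,
            "excluded_patients": [list(x) for x in self.excluded_patients],
        }


def summarize(
    ledger: pd.DataFrame, max_sessions_per_day: int = 2
) -> CorrectnessSummary:
    """Compute every correctness percentage a ledger supports.

    Never-sync patients are excluded from the second self-report figure;
    spurious-counter patients from device-based figures; the notification
    percentage covers only rows where both expected and received counts
    are present.  A metric with no comparable rows is reported as None.
    """
    if len(ledger) == 0:
        raise InvalidInputError("ledger is empty")
    flagged = flag_spurious_device_counts(ledger, max_sessions_per_day)
    excluded: list[tuple[str, str]] = []

    def pct(recorded: float, comparator: float) -> int | None:
        return capture_fraction(int(recorded), int(comparator)) if comparator > 0 else None

    capture_all = pct(
        flagged["system_recorded"].sum(), flagged["self_reported"].sum()
    )

    nonsync = flagged["flags"].apply(lambda f: _has_flag(f, "never_sync"))
    for pid in flagged.loc[nonsync, "patient_id"]:
        excluded.append((str(pid), "never synced; excluded from self-report capture"))
    synced = flagged[~nonsync]
    capture_excl = (
        pct(synced["system_recorded"].sum(), synced["self_reported"].sum())
        if len(synced)
        else None
    )

    spurious = flagged["flags"].apply(lambda f: _has_flag(f, "spurious_device"))
    for pid in flagged.loc[spurious, "patient_id"]:
        excluded.append((str(pid), "spurious device counter; excluded from device comparison"))
    device_rows = flagged[~spurious & flagged["device_logged"].notna()]
    device_total = device_rows["device_logged"].sum()
    if len(device_rows) and device_total > 0:
        capture_device = pct(device_rows["system_recorded"].sum(), device_total)
        overreport = overreport_percent(
            int(device_rows["self_reported"].sum()), int(device_total)
        )
    else:
        capture_device = None
        overreport = None

    notif = flagged[
        flagged["notifications_expected"].notna()
        & flagged["notifications_received"].notna()
    ]
    for pid in flagged.loc[
        flagged["notifications_expected"].isna()
        | flagged["notifications_received"].isna(),
        "patient_id",
    ]:
        excluded.append((str(pid), "incomplete notification log"))
    notif_expected = notif["notifications_expected"].sum()
    notif_pct = (
        pct(notif["notifications_received"].sum(), notif_expected)
        if len(notif) and notif_expected > 0
        else None
    )

    return CorrectnessSummary(
        capture_vs_self_report_pct=capture_all,
        capture_vs_self_report_excl_nonsync_pct=capture_excl,
        capture_vs_device_pct=capture_device,
        overreport_pct=overreport,
        notifications_received_pct=notif_pct,
        excluded_patients=tuple(sorted(excluded)),
    )


def clinician_report(
    timelines: list[PatientTimeline], week_number: int
) -> pd.DataFrame:
    """Adherence-sorted patient table for one week.

    Noncompliant patients come first (they need attention), then almost
    compliant, then compliant; ties break by fewest sessions this week,
    then patient ID.
    """
    if not timelines:
        raise InvalidInputError("need at least one patient timeline")
    rows = []
    for timeline in timelines:
        result = run_check(timeline, week_number, 7)
        sessions = timeline.sessions_in_days(week_number, 1, 7)
        rows.append(
            {
                "patient_id": timeline.patient_id,
                "week": week_number,
                "sessions_this_week": sessions,
                "status": result.status.value,
                "clinician_alert": result.clinician_alert,
                "_order": _STATUS_ORDER[result.status],
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        ["_order", "sessions_this_week", "patient_id"]
    )
    return frame.drop(columns="_order").reset_index(drop=True)


def session_detail(timelines: list[PatientTimeline]) -> pd.DataFrame:
    """Per-session detail rows (one per synced session) for drill-down."""
    rows = []
    for timeline in timelines:
        for record in sorted(timeline.sessions.values(), key=lambda r: r.start_time):
            rows.append(
                {
                    "patient_id": timeline.patient_id,
                    "start_time": record.start_time.isoformat(),
                    "end_time": record.end_time.isoformat(),
                    "avg_peak_voltage": record.avg_peak_voltage,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "start_time", "end_time", "avg_peak_voltage"],
    )
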