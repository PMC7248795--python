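"""End-to-end demo pipeline: simulate, detect, sync, check, dispatch, report.

``run_demo`` wires every stage together in chronological order so that the
point-in-time semantics of the scheduled checks are respected: session
syncs enter patient timelines at their sync instant, adherence checks run
at 21:00 on days 3 and 7 of each patient week against whatever has been
synced by then, and the notification dispatcher ticks hourly across the
whole simulated period.  The run is fully deterministic under a fixed
seed, and writes its artefacts (timelines, server store, dispatch log,
clinician and correctness reports) as plain CSV/JSON files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .adherence import EventType, PatientTimeline, on_session_synced, run_check
from .config import KitConfig
from .notifications import NotificationQueue, hourly_ticks
from .reporting import clinician_report, session_detail, summarize
from .server import ServerStore
from .session_codec import LocalStore, decode_sync_message, frame_sync_message, sync
from .session_detect import SessionRecord, detect_and_log
from .simulate import Cohort, simulate_cohort, render_session_traces

__all__ = ["DemoResult", "run_demo"]

_CHECK_HOUR = time(21, 0)


@dataclass
class DemoResult:
    """Handles on everything the demo produced, plus the output directory."""

    out_dir: Path
    cohort: Cohort
    server: ServerStore
    timelines: dict[str, PatientTimeline]
    queue: NotificationQueue
    sync_reports: list[dict]
    correctness: dict
    #: Map simulator patient id -> anonymous server id.
    id_map: dict[str, str]


def _timeline_rows(cohort: Cohort, id_map: dict[str, str]) -> pd.DataFrame:
    rows = []
    for patient in cohort.patients:
        pid = id_map[patient.patient_id]
        for record in patient.true_sessions:
            rows.append((pid, "true_session", record.start_time.isoformat()))
        for day in patient.self_report_dates:
            rows.append((pid, "self_report", day.isoformat()))
        for when in patient.sync_times:
            rows.append((pid, "session_synced", when.isoformat()))
    return pd.DataFrame(rows, columns=["patient_id", "event_type", "timestamp"])


def run_demo(config: KitConfig, seed: int, out_dir: str | Path) -> DemoResult:
    """Run the full pipeline and write its artefacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = simulate_cohort(config.profiles, config.weeks, seed)
    server = ServerStore()
    enroll_rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    message_rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    queue = NotificationQueue(pools=config.pools)

    id_map: dict[str, str] = {}
    timelines: dict[str, PatientTimeline] = {}
    for patient in cohort.patients:
        anon = server.enroll_patient("clinician-1", patient.start_date, enroll_rng)
        id_map[patient.patient_id] = anon
        timelines[anon] = PatientTimeline(anon, patient.start_date)

    # Detect sessions from rendered traces, then replay syncs and scheduled
    # checks in chronological order.
    events: list[tuple[datetime, int, str, object]] = []
    sync_reports: list[dict] = []
    for patient in cohort.patients:
        anon = id_map[patient.patient_id]
        traces = render_session_traces(patient, config.stimulation)
        detected: list[SessionRecord] = []
        for trace in traces:
            found = detect_and_log(trace, config.detector)
            if len(found) != 1:
                raise RuntimeError(
                    f"stage=detect patient={anon}: expected 1 session per trace, "
                    f"got {len(found)}"
                )
            detected.append(found[0])
        for order, index in enumerate(patient.synced_indices):
            record = detected[index]
            # The device stamps records with its own (possibly drifted) clock.
            offset = patient.device_stamp_offset(patient.true_sessions[index])
            stamped = SessionRecord(
                record.start_time + offset, record.end_time + offset,
                record.avg_peak_voltage,
            )
            events.append((patient.sync_times[order], 0, anon, (patient, stamped)))
        start_midnight = datetime.combine(patient.start_date, time())
        for week in range(1, config.weeks + 1):
            for day in (3, 7):
                when = start_midnight + timedelta(days=(week - 1) * 7 + day - 1)
                events.append(
                    (datetime.combine(when.date(), _CHECK_HOUR), 1, anon, (week, day))
                )

    events.sort(key=lambda item: (item[0], item[1], item[2]))
    for when, kind, anon, payload in events:
        if kind == 0:  # a session sync
            patient, stamped = payload
            # Through the wire: frame, decode, buffer, upload with restamp.
            payload_bytes = frame_sync_message([stamped])
            decoded = decode_sync_message(payload_bytes)
            store = LocalStore()
            store.extend(decoded.records)
            correction = patient.clock_offset_at(when)
            report = sync(
                store,
                server,
                anon,
                restamp=(
                    (lambda r, c=correction: SessionRecord(
                        r.start_time - c, r.end_time - c, r.avg_peak_voltage
                    ))
                    if correction > timedelta(0)
                    else None
                ),
            )
            sync_reports.append({"patient_id": anon, "at": when.isoformat(), **report.to_dict()})
            for key in server.known_start_times(anon):
                record = server.sessions[(anon, key)]
                event = on_session_synced(
                    timelines[anon], SessionRecord.from_dict(record)
                )
                if event is not None:
                    queue.enqueue(anon, event, when, message_rng)
        else:  # a scheduled adherence check
            week, day = payload
            result = run_check(timelines[anon], week, day)
            server.checks.append(result.to_dict())
            for event in result.events():
                queue.enqueue(anon, event, when, message_rng)

    # Hourly dispatch across the simulated period (plus a closing day).
    start = min(p.start_date for p in cohort.patients)
    first_tick = datetime.combine(start, time())
    last_tick = first_tick + timedelta(days=config.weeks * 7 + 1)
    for tick in hourly_ticks(first_tick, last_tick):
        queue.dispatch_pending(tick)

    # Ledger with notification delivery counts filled in from the queue.
    ledger = cohort.ledger()
    ledger["patient_id"] = ledger["patient_id"].map(id_map)
    sent = queue.to_frame()
    if len(sent):
        expected = sent.groupby("patient_id").size()
        received = (
            sent[sent["delivery_status"] == "delivered"].groupby("patient_id").size()
        )
        ledger["notifications_expected"] = (
            ledger["patient_id"].map(expected).astype("Float64")
        )
        ledger["notifications_received"] = (
            ledger["patient_id"].map(received).fillna(0).astype("Float64")
        )
        # Unconfirmable deliveries stay unavailable rather than zero.
        unknown = ledger["patient_id"].isin(queue.unknown_delivery_patients)
        ledger.loc[unknown, "notifications_received"] = pd.NA

    correctness = summarize(ledger).to_dict()

    # -- artefacts ---------------------------------------------------------
    _timeline_rows(cohort, id_map).to_csv(out / "timelines.csv", index=False)
    ledger.to_csv(out / "ledger.csv", index=False)
    queue.to_frame().to_csv(out / "dispatch_log.csv", index=False)
    clinician = clinician_report(list(timelines.values()), config.weeks)
    clinician.to_csv(out / "clinician_report.csv", index=False)
    session_detail(list(timelines.values())).to_csv(
        out / "session_detail.csv", index=False
    )
    (out / "correctness.json").write_text(json.dumps(correctness, indent=2))
    (out / "sync_reports.json").write_text(json.dumps(sync_reports, indent=2))
    server.save_jsonl(out)

    return DemoResult(
        out_dir=out,
        cohort=cohort,
        server=server,
        timelines=timelines,
        queue=queue,
        sync_reports=sync_reports,
        correctness=correctness,
        id_map=id_map,
    )
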