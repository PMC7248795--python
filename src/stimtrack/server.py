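"""In-memory server store with an anonymised, schema-validated data model.

The back end stores only opaque patient identifiers: enrolment mints a
random hex token with no input-derived content, and every write is checked
against a fixed field whitelist so nothing personally identifying can end
up in the store.  Sessions are unique on (patient ID, start time), which
is also the dedup key for repeated syncs.  The store serialises to JSON
lines for inspection and for the demo pipeline's output directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import numpy as np

from .errors import InvalidInputError
from .session_detect import SessionRecord

__all__ = ["ServerStore"]

_SESSION_FIELDS = {"patient_id", "start_time", "end_time", "avg_peak_voltage"}
_PATIENT_FIELDS = {"patient_id", "start_date"}


def _validate_fields(obj: dict, allowed: set[str], kind: str) -> None:
    extra = set(obj) - allowed
    if extra:
        raise InvalidInputError(f"{kind} record carries non-schema fields: {extra}")


@dataclass
class ServerStore:
    """Anonymous-ID patient registry plus session/notification/check logs."""

    clinicians: set[str] = field(default_factory=lambda: {"clinician-1"})
    patients: dict[str, date] = field(default_factory=dict)
    sessions: dict[tuple[str, datetime], dict] = field(default_factory=dict)
    notifications: list[dict] = field(default_factory=list)
    checks: list[dict] = field(default_factory=list)

    # -- enrolment ---------------------------------------------------------

    def enroll_patient(
        self,
        clinician_id: str,
        start_date: date,
        rng: np.random.Generator | None = None,
    ) -> str:
        """Mint a fresh anonymous patient ID (opaque 12-hex-digit token)."""
        if clinician_id not in self.clinicians:
            raise InvalidInputError(f"unknown clinician {clinician_id!r}")
        rng = rng if rng is not None else np.random.default_rng()
        while True:
            token = "".join(f"{b:02x}" for b in rng.integers(0, 256, size=6))
            patient_id = f"pt-{token}"
            if patient_id not in self.patients:
                break
        _validate_fields(
            {"patient_id": patient_id, "start_date": start_date},
            _PATIENT_FIELDS,
            "patient",
        )
        self.patients[patient_id] = start_date
        return patient_id

    # -- sync sink contract ------------------------------------------------

    def known_start_times(self, patient_id: str) -> set[datetime]:
        return {start for pid, start in self.sessions if pid == patient_id}

    def receive(
        self, patient_id: str, records: list[SessionRecord]
    ) -> set[datetime]:
        """Store records, deduplicating on (patient_id, start_time).

        Returns the start times acknowledged (all durably stored records,
        duplicates included — the device may safely delete them).
        """
        acked: set[datetime] = set()
        for record in records:
            key = (patient_id, record.start_time)
            if key not in self.sessions:
                row = {"patient_id": patient_id, **record.to_dict()}
                _validate_fields(row, _SESSION_FIELDS, "session")
                self.sessions[key] = row
            acked.add(record.start_time)
        return acked

    def session_count(self, patient_id: str) -> int:
        return sum(1 for pid, _ in self.sessions if pid == patient_id)

    # -- persistence -------------------------------------------------------

    def save_jsonl(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "patients.jsonl", "w") as fh:
            for pid, start in sorted(self.patients.items()):
                fh.write(
                    json.dumps({"patient_id": pid, "start_date": start.isoformat()})
                    + "\n"
                )
        with open(out / "sessions.jsonl", "w") as fh:
            for key in sorted(self.sessions):
                fh.write(json.dumps(self.sessions[key]) + "\n")
        with open(out / "checks.jsonl", "w") as fh:
            for row in self.checks:
                fh.write(json.dumps(row) + "\n")
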