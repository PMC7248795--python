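"""Fixed-width binary session records, sync framing, local-store semantics.

Device-side telemetry is tiny: each session is exactly 24 bytes — start
time and end time as big-endian unsigned 64-bit milliseconds since the Unix
epoch, then the average peak voltage as a big-endian 64-bit float.  A sync
message is a concatenation of such records terminated by eight 0xFF bytes;
that byte pattern can never open a well-formed record because the
corresponding timestamp is outside the validated range.  The reader
consumes records until it sees the terminator or the (externally clocked)
30-second connection timeout elapses, in which case it salvages the
complete records received so far and flags truncation.

The local store models the device/phone-side buffer: records stay pending
until the server acknowledges them, so a failed upload loses nothing, and
re-uploading an acknowledged record is deduplicated server-side on
(patient ID, start time).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Callable, Iterable, Protocol

from .errors import CorruptStreamError, EncodingError, IncompleteStreamError
from .session_detect import SessionRecord

__all__ = [
    "RECORD_SIZE",
    "TERMINATOR",
    "encode_session",
    "decode_session",
    "frame_sync_message",
    "decode_sync_message",
    "SyncPayload",
    "LocalStore",
    "SyncReport",
    "sync",
]

RECORD_SIZE = 24
TERMINATOR = b"\xff" * 8
_LAYOUT = struct.Struct(">QQd")  # start_ms, end_ms, avg_peak_voltage
_EPOCH = datetime(1970, 1, 1)
# Keep timestamps far below 2**64 so no valid record can start with the
# terminator bytes; this bound is year 9999.
_MAX_MS = int((datetime(9999, 12, 31) - _EPOCH).total_seconds() * 1000)


def _to_ms(when: datetime) -> int:
    ms = round((when - _EPOCH).total_seconds() * 1000)
    if ms < 0 or ms > _MAX_MS:
        raise EncodingError(f"timestamp {when!r} outside representable range")
    return ms


def _from_ms(ms: int) -> datetime:
    return _EPOCH + timedelta(milliseconds=ms)


def encode_session(record: SessionRecord) -> bytes:
    """Serialise one session record into exactly 24 bytes."""
    return _LAYOUT.pack(
        _to_ms(record.start_time), _to_ms(record.end_time), record.avg_peak_voltage
    )


def decode_session(payload: bytes) -> SessionRecord:
    """Inverse of :func:`encode_session`."""
    if len(payload) != RECORD_SIZE:
        raise CorruptStreamError(f"record payload must be {RECORD_SIZE} bytes")
    start_ms, end_ms, voltage = _LAYOUT.unpack(payload)
    if start_ms > _MAX_MS or end_ms > _MAX_MS:
        raise CorruptStreamError("decoded timestamp outside validated range")
    return SessionRecord(_from_ms(start_ms), _from_ms(end_ms), voltage)


def frame_sync_message(records: Iterable[SessionRecord]) -> bytes:
    """Concatenate encoded records and append the end-of-message symbol."""
    return b"".join(encode_session(r) for r in records) + TERMINATOR


@dataclass(frozen=True)
class SyncPayload:
    """Result of reading a sync stream.

    ``truncated`` is set when the stream ended on a timeout before the
    terminator; ``records`` then holds the complete records salvaged.
    """

    records: tuple[SessionRecord, ...]
    truncated: bool


def decode_sync_message(data: bytes, timeout_elapsed: bool = False) -> SyncPayload:
    """Read records until the terminator, or salvage on timeout.

    Raises
    ------
    CorruptStreamError
        The byte count before the terminator is not a multiple of 24.
    IncompleteStreamError
        No terminator and the connection has not timed out.
    """
    records: list[SessionRecord] = []
    pos = 0
    while True:
        rest = data[pos:]
        if rest[: len(TERMINATOR)] == TERMINATOR:
            return SyncPayload(tuple(records), truncated=False)
        if len(rest) >= RECORD_SIZE:
            records.append(decode_session(rest[:RECORD_SIZE]))
            pos += RECORD_SIZE
            continue
        # Partial tail shorter than one record.
        if TERMINATOR in rest:
            raise CorruptStreamError(
                "terminator not aligned to a record boundary"
            )
        if timeout_elapsed:
            return SyncPayload(tuple(records), truncated=True)
        raise IncompleteStreamError("stream ended without terminator or timeout")


class AcknowledgingSink(Protocol):
    """Uplink contract: store records, return acknowledged start times.

    ``receive`` must acknowledge every record it has durably stored,
    including duplicates of records stored earlier (dedup key: patient ID +
    start time), and raise on failure.
    """

    def receive(
        self, patient_id: str, records: list[SessionRecord]
    ) -> set[datetime]:  # pragma: no cover - protocol
        ...


@dataclass
class LocalStore:
    """Device/phone-side buffer of session records awaiting upload."""

    pending: list[SessionRecord] = field(default_factory=list)

    def add(self, record: SessionRecord) -> None:
        if all(r.start_time != record.start_time for r in self.pending):
            self.pending.append(record)

    def extend(self, records: Iterable[SessionRecord]) -> None:
        for record in records:
            self.add(record)


@dataclass(frozen=True)
class SyncReport:
    uploaded: int
    retained: int
    duplicates: int
    failed: bool = False
    truncated: bool = False

    def to_dict(self) -> dict:
        return {
            "uploaded": self.uploaded,
            "retained": self.retained,
            "duplicates": self.duplicates,
            "failed": self.failed,
            "truncated": self.truncated,
        }


def sync(
    store: LocalStore,
    sink: AcknowledgingSink,
    patient_id: str,
    restamp: Callable[[SessionRecord], SessionRecord] | None = None,
) -> SyncReport:
    """Upload pending records; delete only what the sink acknowledged.

    ``restamp`` optionally rewrites record timestamps before upload — the
    remedy for device clock drift, where receive-time stamps assigned by
    the phone replace the device clock.  On sink failure every record is
    retained and the report marks the failure.
    """
    originals = list(store.pending)
    outgoing = [restamp(r) if restamp else r for r in originals]
    try:
        pre_existing = getattr(sink, "known_start_times", lambda pid: set())(
            patient_id
        )
        acked = sink.receive(patient_id, outgoing)
    except Exception:
        return SyncReport(
            uploaded=0, retained=len(store.pending), duplicates=0, failed=True
        )
    duplicates = sum(1 for r in outgoing if r.start_time in pre_existing)
    kept = [
        orig
        for orig, sent in zip(originals, outgoing)
        if sent.start_time not in acked
    ]
    uploaded = len(originals) - len(kept) - duplicates
    store.pending = kept
    return SyncReport(
        uploaded=max(uploaded, 0), retained=len(kept), duplicates=duplicates
    )
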