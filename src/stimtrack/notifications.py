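"""Notification pools, queueing, and the hourly dispatch loop.

Every adherence-engine event maps to a pool of candidate message bodies;
one body is drawn uniformly at random so repeated notifications do not read
as canned.  Events are queued unsent, and a dispatcher that runs on the
hour sends everything created at or before the tick, exactly once.  All
timing is driven by an injected simulated clock, so latency and
exactly-once behaviour are deterministic under test.

Patients whose device ID has been re-associated (log-ins from several
phones) keep receiving notifications, but their deliveries are marked
``delivery-unknown`` instead of ``delivered`` — the log can no longer
confirm receipt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .adherence import EventType
from .errors import ConfigurationError

__all__ = [
    "MessagePool",
    "NotificationEvent",
    "NotificationQueue",
    "DEFAULT_POOLS",
    "load_pools",
    "select_message",
    "hourly_ticks",
]


@dataclass(frozen=True)
class MessagePool:
    """Candidate message bodies for one event type."""

    event_type: EventType
    messages: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.messages) == 0:
            raise ConfigurationError(
                f"message pool for {self.event_type.value} is empty"
            )


_DEFAULT_TEXTS: dict[EventType, tuple[str, ...]] = {
    EventType.AFTER_SESSION: (
        "Session synced - nice work sticking with your stimulation plan!",
        "Another session in the books. Your consistency is paying off.",
        "Well done! Every completed session moves your recovery forward.",
    ),
    EventType.WEEKLY_COMPLIANT: (
        "You hit your weekly session goal - excellent week!",
        "Full marks this week: every prescribed session done. Keep it going!",
        "Goal reached! Your dedication this week really shows.",
    ),
    EventType.WEEKLY_ALMOST: (
        "So close! A couple more sessions next week and you'll hit the goal.",
        "Good effort this week - you nearly reached five sessions. Anything we can help with?",
        "Almost there. Let us know if something is getting in the way of your sessions.",
    ),
    EventType.WEEKLY_NONCOMPLIANT: (
        "We noticed few sessions synced this week. Is anything wrong? We're here to help.",
        "Fewer sessions than planned this week - reach out if the device or app is giving you trouble.",
        "A slow week happens. Let's get back on track - call us if you need a hand.",
    ),
    EventType.MIDWEEK_REMINDER: (
        "Three days without a synced session - don't forget your stimulation therapy!",
        "Just checking in: no sessions synced so far this week. Need any help?",
        "Your week started without a session. A quick one today keeps you on schedule.",
    ),
}

#: Default pools covering every engine event type.
DEFAULT_POOLS: dict[EventType, MessagePool] = {
    et: MessagePool(et, texts) for et, texts in _DEFAULT_TEXTS.items()
}


def load_pools(path: str | Path | None = None) -> dict[EventType, MessagePool]:
    """Load message pools from YAML (keyed by event type), or the defaults.

    Coverage is validated at load time: every engine event type must have a
    nonempty pool.
    """
    if path is None:
        return dict(DEFAULT_POOLS)
    raw = yaml.safe_load(Path(path).read_text())
    pools: dict[EventType, MessagePool] = {}
    for key, messages in (raw or {}).items():
        try:
            event_type = EventType(key)
        except ValueError as exc:
            raise ConfigurationError(f"unknown event type in pools: {key}") from exc
        pools[event_type] = MessagePool(event_type, tuple(messages))
    missing = [et.value for et in EventType if et not in pools]
    if missing:
        raise ConfigurationError(f"pools missing for event types: {missing}")
    return pools


def select_message(pool: MessagePool, rng: np.random.Generator) -> int:
    """Draw a body index uniformly at random from the pool."""
    return int(rng.integers(0, len(pool.messages)))


@dataclass
class NotificationEvent:
    """A queued or sent notification."""

    patient_id: str
    event_type: EventType
    body_index: int
    created_at: datetime
    sent_at: datetime | None = None
    delivery_status: str = "pending"

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "event_type": self.event_type.value,
            "body_index": self.body_index,
            "created_at": self.created_at.isoformat(),
            "sent_at": self.sent_at.isoformat() if self.sent_at else None,
            "delivery_status": self.delivery_status,
        }


@dataclass
class NotificationQueue:
    """Unsent-notification queue with an hourly dispatcher."""

    pools: dict[EventType, MessagePool]
    events: list[NotificationEvent] = field(default_factory=list)
    #: Patients whose device ID was re-associated; deliveries unconfirmable.
    unknown_delivery_patients: set[str] = field(default_factory=set)

    def enqueue(
        self,
        patient_id: str,
        event_type: EventType,
        now: datetime,
        rng: np.random.Generator,
    ) -> NotificationEvent:
        """Create one unsent notification for an engine event."""
        pool = self.pools.get(event_type)
        if pool is None:
            raise ConfigurationError(
                f"no message pool mapped for event type {event_type!r}"
            )
        event = NotificationEvent(
            patient_id=patient_id,
            event_type=event_type,
            body_index=select_message(pool, rng),
            created_at=now,
        )
        self.events.append(event)
        return event

    def dispatch_pending(self, tick: datetime) -> list[NotificationEvent]:
        """Send every unsent notification created at or before ``tick``.

        Each notification is sent exactly once; later ticks never resend.
        """
        sent = []
        for event in self.events:
            if event.sent_at is None and event.created_at <= tick:
                event.sent_at = tick
                event.delivery_status = (
                    "delivery-unknown"
                    if event.patient_id in self.unknown_delivery_patients
                    else "delivered"
                )
                sent.append(event)
        return sent

    def to_frame(self) -> pd.DataFrame:
        """Dispatch log as a DataFrame (one row per notification)."""
        return pd.DataFrame([e.to_dict() for e in self.events])


def hourly_ticks(start: datetime, end: datetime) -> Iterator[datetime]:
    """Hour boundaries strictly after ``start`` up to and including ``end``."""
    tick = start.replace(minute=0, second=0, microsecond=0) + timedelta(hours=1)
    while tick <= end:
        yield tick
        tick += timedelta(hours=1)
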