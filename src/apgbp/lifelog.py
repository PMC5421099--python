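"""Life-log records: XML serialization and store-and-forward delivery.

A monitoring deployment records, besides the estimated blood pressure,
the daily-life covariates that modulate it (weight, meals, sleep times,
activity...).  Records travel as a small element-per-record XML dialect
and are staged in a local outbox so that nothing is lost when the
uplink is down: every record is held until a delivery attempt succeeds
(at-least-once delivery, insertion order preserved).

The XML dialect is defined by its round-trip property rather than an
external schema::

    <lifelog>
      <record kind="weight" user="u01" timestamp="2024-03-04T07:30:00">
        <field name="value">64.2</field>
      </record>
      ...
    </lifelog>
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .errors import SchemaError

__all__ = [
    "KINDS",
    "EVENT_KINDS",
    "LifeLogRecord",
    "write_lifelog_xml",
    "read_lifelog_xml",
    "Outbox",
    "OutboxEntry",
    "DeliveryReport",
]

#: The recordable item kinds (questionnaire, daily and sensor streams).
KINDS = frozenset({
    "height", "age", "weight", "body_temperature", "meal", "bedtime",
    "awaking", "acceleration", "pedometer", "gps", "travel_distance",
    "calorie",
})

#: Kinds that describe events and therefore must carry a timestamp
#: (only the one-off questionnaire items height and age may omit it).
EVENT_KINDS = frozenset(KINDS - {"height", "age"})


@dataclass
class LifeLogRecord:
    """One recorded item, tagged with the user's system ID."""

    user_id: str
    kind: str
    timestamp: str | None = None  # ISO-8601 local time
    payload: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown record kind {self.kind!r}")
        if not self.user_id:
            raise SchemaError("record lacks a user system ID")
        if self.kind in EVENT_KINDS and not self.timestamp:
            raise SchemaError(f"event record of kind {self.kind!r} lacks a timestamp")


def write_lifelog_xml(records: list[LifeLogRecord], path=None) -> bytes:
    """Serialize records (validated) to the XML dialect.

    Returns the document bytes; also writes to ``path`` when given.
    Raises :class:`SchemaError` on an invalid record.
    """
    root = etree.Element("lifelog")
    for rec in records:
        rec.validate()
        el = etree.SubElement(root, "record", kind=rec.kind, user=rec.user_id)
        if rec.timestamp:
            el.set("timestamp", rec.timestamp)
        for key in rec.payload:  # insertion order preserved
            f = etree.SubElement(el, "field", name=str(key))
            f.text = str(rec.payload[key])
    doc = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                         pretty_print=True)
    if path is not None:
        Path(path).write_bytes(doc)
    return doc


def read_lifelog_xml(source) -> tuple[list[LifeLogRecord], list[tuple[int, str]]]:
    """Parse the dialect; inverse of :func:`write_lifelog_xml`.

    Malformed records are not fatal: they are collected into a rejects
    list as ``(position, reason)`` and the valid subset is returned.
    Non-XML input raises ``lxml.etree.XMLSyntaxError``.
    """
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    else:
        root = etree.parse(str(source)).getroot()
    records: list[LifeLogRecord] = []
    rejects: list[tuple[int, str]] = []
    for pos, el in enumerate(root.iter("record")):
        rec = LifeLogRecord(
            user_id=el.get("user", ""),
            kind=el.get("kind", ""),
            timestamp=el.get("timestamp"),
            payload={f.get("name"): f.text for f in el.iter("field")},
        )
        try:
            rec.validate()
        except SchemaError as exc:
            rejects.append((pos, str(exc)))
            continue
        records.append(rec)
    return records, rejects


@dataclass
class OutboxEntry:
    record: LifeLogRecord
    status: str = "pending"  # pending | sent
    attempts: int = 0


@dataclass
class DeliveryReport:
    sent: int
    pending: int
    attempts: int


class Outbox:
    """Durable store-and-forward queue for life-log records.

    Records are enqueued locally before any transmission, so data is
    held even while the sink (the uplink) is failing; a later drain
    retries every pending entry in insertion order.  Each entry is
    marked sent exactly once, after the first successful attempt.
    Backed by a JSON file when ``path`` is given, else in memory.
    """

    def __init__(self, path=None):
        self.path = Path(path) if path is not None else None
        self.entries: list[OutboxEntry] = []
        if self.path is not None and self.path.exists():
            try:
                doc = json.loads(self.path.read_text())
                self.entries = [
                    OutboxEntry(record=LifeLogRecord(**e["record"]),
                                status=e["status"], attempts=e["attempts"])
                    for e in doc
                ]
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise SchemaError(f"corrupt outbox store at {self.path}: {exc}") from exc

    def _flush(self) -> None:
        if self.path is None:
            return
        doc = [{"record": {"user_id": e.record.user_id, "kind": e.record.kind,
                           "timestamp": e.record.timestamp,
                           "payload": e.record.payload},
                "status": e.status, "attempts": e.attempts}
               for e in self.entries]
        self.path.write_text(json.dumps(doc, indent=1))

    def enqueue(self, record: LifeLogRecord) -> None:
        record.validate()
        self.entries.append(OutboxEntry(record=record))
        self._flush()

    def drain(self, sink) -> DeliveryReport:
        """Attempt delivery of every pending entry, in insertion order.

        ``sink`` is a callable receiving the record; raising marks the
        attempt failed and the entry stays pending for the next drain.
        """
        attempts = 0
        for entry in self.entries:
            if entry.status != "pending":
                continue
            entry.attempts += 1
            attempts += 1
            try:
                sink(entry.record)
            except Exception:  # noqa: BLE001 - any sink failure means retry later
                continue
            entry.status = "sent"
        self._flush()
        sent = sum(1 for e in self.entries if e.status == "sent")
        pending = len(self.entries) - sent
        return DeliveryReport(sent=sent, pending=pending, attempts=attempts)
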