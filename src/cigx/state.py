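"""Timestamped patient-state store and encounter event streams.

The store is an append-only log of observations under a simulated clock.
The engine never reads the log directly: it takes a :func:`snapshot`, which
binds each semantic path to the value of its latest *visible* observation
(timestamp at or before the clock; ties broken by insertion order, later
wins).  Observations timestamped in the future are recorded but invisible
until the clock catches up, which keeps time-triggered behaviour
deterministic and replayable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, List, Optional, Union

from lxml import etree

from .errors import ClockRegression, ParseError
from .expr import NS, Bindings, LiteralValue

PROVENANCE_KINDS = ("reported", "diagnostic_test", "treatment_result", "derived")

EPOCH = datetime(1970, 1, 1)

_STREAM_HEADER = "timestamp\tpath\ttype\tvalue\tprovenance"


@dataclass(frozen=True)
class Observation:
    path: str
    value: LiteralValue
    timestamp: datetime
    provenance: str = "reported"

    def __post_init__(self):
        if self.provenance not in PROVENANCE_KINDS:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not isinstance(self.timestamp, datetime):
            raise ValueError("timestamp must be a datetime")


@dataclass(frozen=True)
class TimeAdvance:
    """A pure clock-advance event (enables time_passage triggers)."""

    at: datetime


Event = Union[Observation, TimeAdvance]


class StateStore:
    """Append-only observation log plus a simulated clock."""

    def __init__(self, clock: datetime = EPOCH):
        self.observations: List[Observation] = []
        self.clock = clock

    def record_observation(self, obs: Observation) -> "StateStore":
        self.observations.append(obs)
        return self

    def advance_clock(self, new_instant: datetime) -> "StateStore":
        if new_instant < self.clock:
            raise ClockRegression(
                f"clock cannot move from {self.clock.isoformat()} back to "
                f"{new_instant.isoformat()}"
            )
        self.clock = new_instant
        return self

    def snapshot(self) -> Bindings:
        """Latest visible value per path; never-observed paths are absent."""
        entries = {}
        for obs in self.observations:  # insertion order; later wins
            if obs.timestamp <= self.clock:
                entries[obs.path] = obs.value
        return Bindings(entries)

    def replay(self) -> "StateStore":
        """Rebuild an identical store from the log (event-sourcing check)."""
        fresh = StateStore()
        for obs in self.observations:
            fresh.record_observation(obs)
        fresh.clock = self.clock
        return fresh


def record_observation(store: StateStore, obs: Observation) -> StateStore:
    return store.record_observation(obs)


def snapshot(store: StateStore) -> Bindings:
    return store.snapshot()


def advance_clock(store: StateStore, new_instant: datetime) -> StateStore:
    return store.advance_clock(new_instant)


# --------------------------------------------------------------------------
# Encounter event-stream files
#
# Text form: tab-separated, one record per line, header required.  Columns
# are (timestamp, path, type, value, provenance).  A pure clock advance is
# written with type "time" and empty path/value/provenance fields.  An XML
# form (<events> in the document namespace) is also accepted.


def events_to_text(events: Iterable[Event]) -> str:
    lines = [_STREAM_HEADER]
    for ev in events:
        if isinstance(ev, TimeAdvance):
            lines.append(f"{ev.at.isoformat()}\t\ttime\t\t")
        else:
            lines.append(
                "\t".join(
                    (
                        ev.timestamp.isoformat(),
                        ev.path,
                        ev.value.kind,
                        ev.value.to_text(),
                        ev.provenance,
                    )
                )
            )
    return "\n".join(lines) + "\n"


def events_from_text(text: str) -> List[Event]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != _STREAM_HEADER:
        raise ParseError("event stream missing header line")
    events: List[Event] = []
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(f"line {i}: expected 5 tab-separated fields")
        ts, path, kind, value, provenance = fields
        try:
            instant = datetime.fromisoformat(ts)
        except ValueError:
            raise ParseError(f"line {i}: bad timestamp {ts!r}") from None
        if kind == "time":
            events.append(TimeAdvance(instant))
        else:
            events.append(
                Observation(
                    path=path,
                    value=LiteralValue.from_text(kind, value),
                    timestamp=instant,
                    provenance=provenance,
                )
            )
    return events


def events_from_xml(xml_bytes: bytes) -> List[Event]:
    try:
        root = etree.fromstring(xml_bytes)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from None
    q = "{%s}" % NS
    events: List[Event] = []
    for child in root:
        if not isinstance(child.tag, str):
            continue
        name = etree.QName(child).localname
        if name == "time-advance":
            events.append(TimeAdvance(datetime.fromisoformat(child.get("at"))))
        elif name == "observation":
            events.append(
                Observation(
                    path=child.get("path"),
                    value=LiteralValue.from_text(child.get("type"), child.get("value")),
                    timestamp=datetime.fromisoformat(child.get("timestamp")),
                    provenance=child.get("provenance"),
                )
            )
        else:
            raise ParseError(f"unknown event element <{name}>")
    return events


def read_events_file(path) -> List[Event]:
    with open(path, "rb") as fh:
        data = fh.read()
    if data.lstrip().startswith(b"<"):
        return events_from_xml(data)
    return events_from_text(data.decode("utf-8"))


def write_events_file(events: Iterable[Event], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(events_to_text(events))
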