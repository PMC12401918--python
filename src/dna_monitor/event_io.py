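"""Reading, validating and writing CASAS-style annotated event logs.

The CASAS smart-home testbeds record one sensor event per line, whitespace
delimited::

    2016-12-23 19:35:00.000000 M003 ON Sleep begin
    2016-12-23 19:35:02        D001 OPEN

Four fields are mandatory (date, time, sensor id, status); an activity label
and a ``begin``/``end`` marker are optional annotations.  Begin/end marker
pairs delimit labeled activity intervals (Sleep, Cook_Breakfast, ...), which
downstream modules aggregate into daily time budgets and nightly sleep
sessions.

Malformed lines are collected into a validation report rather than raised one
by one; a file where the majority of lines fail to parse is rejected outright
as being in the wrong dialect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "SensorEvent",
    "ActivityInterval",
    "EventStream",
    "ValidationReport",
    "PairingReport",
    "EventParseError",
    "EventFormatError",
    "parse_event_line",
    "read_event_log",
    "write_event_log",
    "format_event_line",
    "pair_activity_intervals",
]

Marker = Literal["begin", "end"]

#: Clock time used to assign sleep-type intervals to a "night": an interval
#: starting after noon belongs to that calendar date, one starting before
#: noon to the previous date.  This is the standard actigraphy convention for
#: nights that wrap midnight.
NOON_ANCHOR = time(12, 0)

#: Calendar-day anchor (midnight split) used for daytime activity budgets.
MIDNIGHT_ANCHOR = time(0, 0)


class EventParseError(ValueError):
    """A single event line could not be parsed.

    Carries the 1-based line number (when known) and the offending field so
    validation reports can cite the exact location.
    """

    def __init__(self, message: str, line_number: int | None = None, field: str | None = None):
        self.line_number = line_number
        self.field = field
        prefix = f"line {line_number}: " if line_number is not None else ""
        super().__init__(f"{prefix}{message}")


class EventFormatError(ValueError):
    """The file as a whole does not look like a CASAS-dialect event log."""


@dataclass(frozen=True)
class SensorEvent:
    """One timestamped sensor record, optionally annotated with an activity."""

    timestamp: datetime
    sensor_id: str
    status: str
    activity_label: str | None = None
    marker: Marker | None = None

    def __post_init__(self) -> None:
        if self.marker is not None and self.activity_label is None:
            raise ValueError("marker present without an activity label")
        if self.marker not in (None, "begin", "end"):
            raise ValueError(f"marker must be 'begin' or 'end', got {self.marker!r}")


@dataclass(frozen=True)
class ActivityInterval:
    """A begin/end-paired labeled activity span, assigned to a source day."""

    activity: str
    start: datetime
    end: datetime
    source_day: date

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval for {self.activity!r} has non-positive duration "
                f"({self.start} .. {self.end})"
            )

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class ValidationReport:
    """Outcome of reading a log: skipped lines and ordering violations."""

    n_lines: int = 0
    n_parsed: int = 0
    malformed: list[tuple[int, str]] = field(default_factory=list)
    order_violations: list[int] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.malformed)

    def summary(self) -> str:
        return (
            f"{self.n_parsed}/{self.n_lines} lines parsed, "
            f"{self.n_skipped} malformed, "
            f"{len(self.order_violations)} timestamp-order violations"
        )


@dataclass
class PairingReport:
    """Unmatched or irregular begin/end markers found while pairing."""

    orphan_begins: list[tuple[str, datetime]] = field(default_factory=list)
    orphan_ends: list[tuple[str, datetime]] = field(default_factory=list)
    nested_begins: list[tuple[str, datetime]] = field(default_factory=list)


@dataclass
class EventStream:
    """An ordered sequence of sensor events plus where they came from."""

    events: list[SensorEvent]
    provenance: str = "<memory>"
    report: ValidationReport = field(default_factory=ValidationReport)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def parse_event_line(line: str, line_number: int | None = None) -> SensorEvent:
    """Parse one whitespace-delimited CASAS event line.

    Field order is ``date time sensor_id status [activity] [marker]``; both
    plain-second and fractional-second timestamps are accepted.
    """
    fields = line.split()
    if len(fields) < 4:
        raise EventParseError(
            f"expected at least 4 whitespace-separated fields, got {len(fields)}",
            line_number,
            field="line",
        )
    try:
        timestamp = datetime.fromisoformat(f"{fields[0]} {fields[1]}")
    except ValueError as exc:
        raise EventParseError(
            f"malformed timestamp {fields[0]!r} {fields[1]!r}: {exc}",
            line_number,
            field="timestamp",
        ) from None
    sensor_id, status = fields[2], fields[3]
    activity = fields[4] if len(fields) >= 5 else None
    marker: Marker | None = None
    if len(fields) >= 6:
        if fields[5] not in ("begin", "end"):
            raise EventParseError(
                f"marker must be 'begin' or 'end', got {fields[5]!r}",
                line_number,
                field="marker",
            )
        marker = fields[5]  # type: ignore[assignment]
    if len(fields) > 6:
        raise EventParseError(
            f"unexpected trailing fields: {fields[6:]!r}", line_number, field="line"
        )
    return SensorEvent(timestamp, sensor_id, status, activity, marker)


def format_event_line(event: SensorEvent) -> str:
    """Render an event back into the whitespace-delimited dialect."""
    ts = event.timestamp.strftime("%Y-%m-%d %H:%M:%S.%f")
    parts = [ts, event.sensor_id, event.status]
    if event.activity_label is not None:
        parts.append(event.activity_label)
        if event.marker is not None:
            parts.append(event.marker)
    return " ".join(parts)


def read_event_log(path: str | Path | io.TextIOBase, *, max_malformed_fraction: float = 0.5) -> EventStream:
    """Read a CASAS-dialect event log into an :class:`EventStream`.

    All parseable lines become events in file order.  Malformed lines and
    timestamp-order violations are recorded in the stream's validation report
    instead of being silently dropped or reordered.  If more than
    ``max_malformed_fraction`` of non-blank lines fail to parse the file is
    rejected as being in the wrong dialect.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.readlines()
        provenance = getattr(path, "name", "<stream>")
    else:
        provenance = str(path)
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.readlines()

    report = ValidationReport()
    events: list[SensorEvent] = []
    last_ts: datetime | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        report.n_lines += 1
        try:
            event = parse_event_line(line, line_number=lineno)
        except EventParseError as exc:
            report.malformed.append((lineno, str(exc)))
            continue
        if last_ts is not None and event.timestamp < last_ts:
            report.order_violations.append(lineno)
        last_ts = event.timestamp
        events.append(event)
        report.n_parsed += 1

    if report.n_lines > 0 and report.n_skipped / report.n_lines > max_malformed_fraction:
        raise EventFormatError(
            f"{report.n_skipped} of {report.n_lines} lines are malformed; "
            f"{provenance!r} does not look like a CASAS-dialect event log"
        )
    return EventStream(events=events, provenance=provenance, report=report)


def write_event_log(stream: EventStream | Iterable[SensorEvent], path: str | Path) -> None:
    events = stream.events if isinstance(stream, EventStream) else list(stream)
    with open(path, "w", encoding="utf-8") as fh:
        for event in events:
            fh.write(format_event_line(event) + "\n")


def assign_day(instant: datetime, anchor: time) -> date:
    """Map an instant to its anchored day.

    With a midnight anchor this is the calendar date; with a noon anchor,
    instants before 12:00 belong to the previous date (so a night wrapping
    midnight is one unit).
    """
    shifted = instant - timedelta(
        hours=anchor.hour, minutes=anchor.minute, seconds=anchor.second
    )
    return shifted.date()


def pair_activity_intervals(
    stream: EventStream | Sequence[SensorEvent],
    day_anchor: time = MIDNIGHT_ANCHOR,
    *,
    report: PairingReport | None = None,
) -> list[ActivityInterval]:
    """Match begin/end markers of the same activity label into intervals.

    Each ``begin`` is matched to the next ``end`` carrying the same label;
    nested begins of one label are closed in LIFO order and noted in the
    report.  Orphan begins (no end before the stream runs out) and orphan
    ends (end before any begin) are reported, never raised.  Interleaved
    unannotated sensor events are ignored by the pairing.

    Intervals are assigned wholly to the anchored day containing their start.
    Pass a :class:`PairingReport` to collect the irregularities.
    """
    events = stream.events if isinstance(stream, EventStream) else list(stream)
    if report is None:
        report = PairingReport()
    open_begins: dict[str, list[datetime]] = {}
    intervals: list[ActivityInterval] = []
    for event in events:
        if event.marker is None or event.activity_label is None:
            continue
        label = event.activity_label
        if event.marker == "begin":
            stack = open_begins.setdefault(label, [])
            if stack:
                report.nested_begins.append((label, event.timestamp))
            stack.append(event.timestamp)
        else:  # end
            stack = open_begins.get(label)
            if not stack:
                report.orphan_ends.append((label, event.timestamp))
                continue
            start = stack.pop()  # LIFO for nested begins
            if event.timestamp <= start:
                report.orphan_ends.append((label, event.timestamp))
                continue
            intervals.append(
                ActivityInterval(
                    activity=label,
                    start=start,
                    end=event.timestamp,
                    source_day=assign_day(start, day_anchor),
                )
            )
    for label, stack in open_begins.items():
        for ts in stack:
            report.orphan_begins.append((label, ts))
    intervals.sort(key=lambda iv: (iv.start, iv.activity))
    return intervals
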