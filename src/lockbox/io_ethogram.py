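"""Reading and writing contact-event logs and per-episode metric tables.

An event log records every coded physical contact a subject made with a
lockbox component (wheel, bar, door, or any other surface) during timed test
sessions.  The on-disk format is a plain UTF-8, comma-separated file with a
required header::

    subject_id,session_index,initial_state,session_duration_s,time_s,component,opens_lock

One row per contact; a session with no contacts at all is encoded as a single
row whose ``time_s``, ``component`` and ``opens_lock`` cells are empty (such
sessions still contribute observation time).  Times are decimal seconds from
the start of the session, booleans are the lowercase literals ``true`` /
``false``, and floats are serialised with Python's shortest round-tripping
representation so that ``read(write(x)) == x`` bit-exactly.

Observation software such as BORIS can be mapped onto this dialect by
exporting the coded events per observation and renaming columns:
observation id -> ``subject_id`` + ``session_index``, media time ->
``time_s``, behavior/modifier -> ``component`` and ``opens_lock``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import FormatError, ValidationError

#: Components a contact can be coded on.  ``other`` covers contacts with any
#: non-lock surface (frame, window, table, ...).
COMPONENTS: tuple[str, ...] = ("wheel", "bar", "door", "other")

#: The three locks, in the order they must be opened.
LOCKS: tuple[str, ...] = ("wheel", "bar", "door")

#: Valid ``initial_state`` labels for a session (a session can never start
#: already solved).
INITIAL_STATES: tuple[str, ...] = ("wheel_locked", "bar_locked", "door_locked")

EVENT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "session_index",
    "initial_state",
    "session_duration_s",
    "time_s",
    "component",
    "opens_lock",
)

METRICS_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "solution_index",
    "T_s",
    "n_a",
    "n_c",
    "n_w",
    "n_b",
    "n_d",
    "M",
    "E",
    "delta_s",
    "complete",
)


@dataclass(frozen=True)
class ContactEvent:
    """One coded physical contact with a lockbox component.

    Parameters
    ----------
    time_s
        Seconds from the start of the session (non-negative).
    component
        One of :data:`COMPONENTS`.
    opens_lock
        True when this contact opened the component it touched.  Only lock
        components can open.
    """

    time_s: float
    component: str
    opens_lock: bool = False

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValidationError(
                f"unknown component {self.component!r}; expected one of {COMPONENTS}"
            )
        if not (self.time_s >= 0):
            raise ValidationError(f"event time must be >= 0, got {self.time_s!r}")
        if self.opens_lock and self.component not in LOCKS:
            raise ValidationError(
                f"opens_lock=true is only valid on a lock component, got {self.component!r}"
            )


@dataclass
class SessionRecord:
    """One test session: metadata plus its ordered contact events.

    ``duration_s`` is the observed session length (capped at 900 s in the
    study design unless the box was solved earlier).  ``initial_state`` is the
    lockbox state at session start; the default protocol re-locks everything
    (``wheel_locked``) but mid-state starts occur when a subject continues an
    unfinished episode with the wheel already removed.
    """

    subject_id: str
    session_index: int
    duration_s: float
    initial_state: str = "wheel_locked"
    events: list[ContactEvent] = field(default_factory=list)

    def validate(self) -> None:
        """Raise :class:`ValidationError` if any session invariant is broken."""
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")
        if self.session_index < 1:
            raise ValidationError(
                f"session_index must be a positive integer, got {self.session_index}"
            )
        if self.initial_state not in INITIAL_STATES:
            raise ValidationError(
                f"initial_state {self.initial_state!r} not one of {INITIAL_STATES} "
                f"(subject {self.subject_id!r}, session {self.session_index})"
            )
        if self.duration_s < 0:
            raise ValidationError(
                f"duration_s must be >= 0 (subject {self.subject_id!r}, "
                f"session {self.session_index})"
            )
        prev = None
        for ev in self.events:
            if prev is not None and not (ev.time_s > prev):
                raise ValidationError(
                    f"event times must be strictly increasing within a session "
                    f"(subject {self.subject_id!r}, session {self.session_index}, "
                    f"time {ev.time_s!r} after {prev!r})"
                )
            prev = ev.time_s
        if self.events and self.duration_s < self.events[-1].time_s:
            raise ValidationError(
                f"duration_s ({self.duration_s!r}) is before the last event "
                f"({self.events[-1].time_s!r}) (subject {self.subject_id!r}, "
                f"session {self.session_index})"
            )


def _fmt_float(x: float) -> str:
    # repr of a Python float is the shortest string that round-trips.
    return repr(float(x))


def _parse_float(cell: str, what: str, where: str) -> float:
    try:
        value = float(cell)
    except ValueError:
        raise FormatError(f"cannot parse {what} {cell!r} as a number ({where})") from None
    if value != value:  # NaN
        raise FormatError(f"{what} may not be NaN ({where})")
    return value


def _parse_bool(cell: str, where: str) -> bool:
    if cell == "true":
        return True
    if cell == "false":
        return False
    raise FormatError(
        f"cannot parse opens_lock {cell!r}; expected 'true' or 'false' ({where})"
    )


def read_event_log(path: str | Path) -> list[SessionRecord]:
    """Read an event-log CSV into validated session records.

    Returns the sessions sorted by ``(subject_id, session_index)``.  All type
    invariants are checked; violations raise :class:`ValidationError` (or
    :class:`FormatError` for structural problems) naming the offending
    subject, session and row.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, header row required") from None
        missing = [c for c in EVENT_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
        col = {name: header.index(name) for name in EVENT_COLUMNS}

        sessions: dict[tuple[str, int], SessionRecord] = {}
        empty_marker: set[tuple[str, int]] = set()
        for rownum, row in enumerate(reader, start=2):
            if not row or all(cell == "" for cell in row):
                continue
            where = f"{path} row {rownum}"
            if len(row) < len(header):
                raise FormatError(f"{where}: expected {len(header)} cells, got {len(row)}")
            subject = row[col["subject_id"]]
            if not subject:
                raise FormatError(f"{where}: empty subject_id")
            try:
                session_index = int(row[col["session_index"]])
            except ValueError:
                raise FormatError(
                    f"{where}: cannot parse session_index {row[col['session_index']]!r}"
                ) from None
            initial_state = row[col["initial_state"]]
            duration = _parse_float(row[col["session_duration_s"]], "session_duration_s", where)

            key = (subject, session_index)
            rec = sessions.get(key)
            if rec is None:
                rec = SessionRecord(
                    subject_id=subject,
                    session_index=session_index,
                    duration_s=duration,
                    initial_state=initial_state,
                    events=[],
                )
                sessions[key] = rec
            else:
                if rec.initial_state != initial_state:
                    raise ValidationError(
                        f"{where}: initial_state {initial_state!r} conflicts with "
                        f"{rec.initial_state!r} for subject {subject!r}, session {session_index}"
                    )
                if rec.duration_s != duration:
                    raise ValidationError(
                        f"{where}: session_duration_s {duration!r} conflicts with "
                        f"{rec.duration_s!r} for subject {subject!r}, session {session_index}"
                    )

            time_cell = row[col["time_s"]]
            comp_cell = row[col["component"]]
            opens_cell = row[col["opens_lock"]]
            if time_cell == "" and comp_cell == "" and opens_cell == "":
                # explicit empty-session marker
                if rec.events or key in empty_marker:
                    raise ValidationError(
                        f"{where}: duplicate or conflicting empty-session row for "
                        f"subject {subject!r}, session {session_index}"
                    )
                empty_marker.add(key)
                continue
            if key in empty_marker:
                raise ValidationError(
                    f"{where}: event row for subject {subject!r}, session "
                    f"{session_index} after an empty-session marker"
                )
            time_s = _parse_float(time_cell, "time_s", where)
            opens = _parse_bool(opens_cell, where)
            try:
                event = ContactEvent(time_s=time_s, component=comp_cell, opens_lock=opens)
            except ValidationError as exc:
                raise ValidationError(
                    f"{where} (subject {subject!r}, session {session_index}): {exc}"
                ) from None
            if rec.events and not (event.time_s > rec.events[-1].time_s):
                raise ValidationError(
                    f"{where}: non-increasing time_s {event.time_s!r} (previous "
                    f"{rec.events[-1].time_s!r}) for subject {subject!r}, "
                    f"session {session_index}"
                )
            rec.events.append(event)

    ordered = sorted(sessions.values(), key=lambda r: (r.subject_id, r.session_index))
    for rec in ordered:
        rec.validate()
    return ordered


def write_event_log(records: Iterable[SessionRecord], path: str | Path) -> None:
    """Write session records as an event-log CSV (sorted, round-trippable)."""
    records = sorted(records, key=lambda r: (r.subject_id, r.session_index))
    for rec in records:
        rec.validate()
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(EVENT_COLUMNS)
        for rec in records:
            meta = [
                rec.subject_id,
                str(rec.session_index),
                rec.initial_state,
                _fmt_float(rec.duration_s),
            ]
            if not rec.events:
                writer.writerow(meta + ["", "", ""])
                continue
            for ev in rec.events:
                writer.writerow(
                    meta
                    + [
                        _fmt_float(ev.time_s),
                        ev.component,
                        "true" if ev.opens_lock else "false",
                    ]
                )


def sessions_by_subject(records: Sequence[SessionRecord]) -> dict[str, list[SessionRecord]]:
    """Group sorted session records into per-subject ordered lists."""
    grouped: dict[str, list[SessionRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.subject_id, []).append(rec)
    for sessions in grouped.values():
        sessions.sort(key=lambda r: r.session_index)
    return grouped


def write_metrics_table(records: Iterable, path: str | Path) -> None:
    """Write per-episode decomposition records as a metrics CSV.

    One row per (subject, solution index), sorted, with columns
    ``subject_id, solution_index, T_s, n_a, n_c, n_w, n_b, n_d, M, E,
    delta_s, complete``.  Accepts the ``DecompositionRecord`` objects produced
    by :mod:`lockbox.decomposition`.
    """
    rows = sorted(records, key=lambda r: (r.subject_id, r.solution_index))
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(METRICS_COLUMNS)
        for r in rows:
            writer.writerow(
                [
                    r.subject_id,
                    str(r.solution_index),
                    _fmt_float(r.T_s),
                    str(r.n_a),
                    str(r.n_c),
                    str(r.counts.n_correct["wheel"]),
                    str(r.counts.n_correct["bar"]),
                    str(r.counts.n_correct["door"]),
                    _fmt_float(r.M),
                    str(r.E),
                    _fmt_float(r.delta_s),
                    "true" if r.complete else "false",
                ]
            )
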