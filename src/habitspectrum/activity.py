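"""Domain model for activity-of-daily-living (ADL) logs.

An activity log is a flat table of performed activities: who did what, when,
for how long.  Activities are referenced through an :class:`ActivityRegistry`
that maps each activity name to a positive integer ID — the quantity that
later enters the behavioral spectrum as a harmonic phase.  Logs are grouped
into :class:`HabitSequence` objects, one per observation window (a free-form
session, or a morning/afternoon/night phase of the day), which are the unit
of spectral encoding.

Log files are plain CSV with header
``subject,date,clock_time,window,activity,duration_min``; the ``activity``
column accepts either a registered name or its integer ID.  Registries are
CSV with header ``name,id`` (the ``id`` column optional).
"""

from __future__ import annotations

import datetime as _dt
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ActivityRegistry",
    "ActivityEvent",
    "HabitSequence",
    "PhaseWindows",
    "DEFAULT_PHASE_WINDOWS",
    "load_registry",
    "read_activity_log",
    "write_activity_log",
    "extract_sequences",
]

LOG_COLUMNS = ["subject", "date", "clock_time", "window", "activity", "duration_min"]


class RegistryFormatError(ValueError):
    """Malformed registry source (duplicate or invalid entries)."""


class LogFormatError(ValueError):
    """Malformed activity-log file."""


@dataclass(frozen=True)
class ActivityRegistry:
    """Bijection between activity names and positive integer activity IDs."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        ids = [i for _, i in self.entries]
        for name, id_ in self.entries:
            if not name:
                raise RegistryFormatError("empty activity name")
            if not isinstance(id_, int) or id_ < 1:
                raise RegistryFormatError(
                    f"activity {name!r} has non-positive ID {id_!r}; IDs must be >= 1"
                )
        dup_names = {n for n in names if names.count(n) > 1}
        if dup_names:
            raise RegistryFormatError(f"duplicate activity names: {sorted(dup_names)}")
        dup_ids = {i for i in ids if ids.count(i) > 1}
        if dup_ids:
            raise RegistryFormatError(f"duplicate activity IDs: {sorted(dup_ids)}")
        object.__setattr__(self, "_by_name", dict(self.entries))
        object.__setattr__(self, "_by_id", {i: n for n, i in self.entries})

    def id_of(self, name: str) -> int:
        return self._by_name[name]

    def name_of(self, id_: int) -> str:
        return self._by_id[id_]

    def __contains__(self, key: object) -> bool:
        return key in self._by_name or key in self._by_id

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def ids(self) -> list[int]:
        return [i for _, i in self.entries]

    def to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(self.entries, columns=["name", "id"]).to_csv(path, index=False)


@dataclass(frozen=True)
class ActivityEvent:
    """One performed activity: a row of the log."""

    subject: str
    date: _dt.date
    order_index: int
    activity_id: int
    duration: float
    clock_time: _dt.time | None = None
    window: str | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.activity_id < 1:
            raise ValueError(f"activity_id must be >= 1, got {self.activity_id}")
        if self.order_index < 0:
            raise ValueError("order_index must be >= 0")


@dataclass(frozen=True)
class HabitSequence:
    """One observation window's ordered (activity ID, duration) pairs.

    This is the unit that becomes one behavioral-spectrum signal: the n-th
    activity contributes harmonic n+1, with its ID as phase and its duration
    in minutes as amplitude.
    """

    subject: str
    window_label: str
    ids: tuple[int, ...]
    durations: tuple[float, ...]
    date: _dt.date | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.durations):
            raise ValueError("ids and durations must have equal length")
        if any(d <= 0 for d in self.durations):
            raise ValueError("all durations must be > 0")
        if any(i < 1 for i in self.ids):
            raise ValueError("all activity IDs must be >= 1")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def key(self) -> str:
        d = self.date.isoformat() if self.date is not None else "-"
        return f"{self.subject}|{d}|{self.window_label}"


def _parse_time(value: str) -> _dt.time:
    return _dt.time.fromisoformat(value)


@dataclass(frozen=True)
class PhaseWindows:
    """Partition of the 24-hour day into labelled, half-open time windows.

    A window may wrap midnight (start > end).  Membership uses the half-open
    convention [start, end): an event whose clock time falls exactly on a
    boundary belongs to the window that starts there.
    """

    boundaries: tuple[tuple[str, _dt.time, _dt.time], ...]

    def __post_init__(self) -> None:
        labels = [b[0] for b in self.boundaries]
        if len(set(labels)) != len(labels):
            raise ValueError("window labels must be unique")
        # coverage check: total minutes must sum to 24 h with no overlap
        total = 0
        for _, start, end in self.boundaries:
            s = start.hour * 60 + start.minute
            e = end.hour * 60 + end.minute
            total += (e - s) % (24 * 60) or 24 * 60
        if total != 24 * 60:
            raise ValueError("phase windows must jointly cover 24 h without overlap")

    @property
    def labels(self) -> list[str]:
        return [b[0] for b in self.boundaries]

    def label_for(self, t: _dt.time) -> str:
        minutes = t.hour * 60 + t.minute
        for label, start, end in self.boundaries:
            s = start.hour * 60 + start.minute
            e = end.hour * 60 + end.minute
            if s <= e:
                if s <= minutes < e:
                    return label
            else:  # wraps midnight
                if minutes >= s or minutes < e:
                    return label
        raise ValueError(f"time {t} not covered by any window")  # pragma: no cover

    @classmethod
    def from_spec(cls, spec: Sequence[tuple[str, str, str]]) -> "PhaseWindows":
        return cls(tuple((lab, _parse_time(s), _parse_time(e)) for lab, s, e in spec))


#: Morning/afternoon/night split of the day, wrapping midnight for night.
DEFAULT_PHASE_WINDOWS = PhaseWindows.from_spec(
    [("morning", "05:00", "12:00"), ("afternoon", "12:00", "18:00"), ("night", "18:00", "05:00")]
)


def load_registry(
    source: str | os.PathLike | Mapping[str, int] | Iterable[str],
) -> ActivityRegistry:
    """Build an :class:`ActivityRegistry` from a CSV path, mapping, or name list.

    A CSV source has header ``name,id`` or just ``name``; when IDs are absent
    they are assigned 1..N in order of appearance.
    """
    if isinstance(source, Mapping):
        entries = [(str(n), int(i)) for n, i in source.items()]
    elif isinstance(source, (str, os.PathLike)):
        df = pd.read_csv(source, dtype={"name": str})
        if "name" not in df.columns:
            raise RegistryFormatError("registry CSV must have a 'name' column")
        if "id" in df.columns:
            entries = [(str(n), int(i)) for n, i in zip(df["name"], df["id"])]
        else:
            entries = [(str(n), i + 1) for i, n in enumerate(df["name"])]
    else:
        entries = [(str(n), i + 1) for i, n in enumerate(source)]
    return ActivityRegistry(tuple(entries))


def _resolve_activity(value: object, registry: ActivityRegistry) -> int:
    """Map a log-cell value (name or integer ID) to an activity ID."""
    text = str(value).strip()
    try:
        id_ = int(text)
    except ValueError:
        id_ = None
    if id_ is not None:
        if id_ not in registry:
            raise LogFormatError(f"unknown activity ID {id_}")
        return id_
    if text not in registry:
        raise LogFormatError(f"unknown activity name {text!r}")
    return registry.id_of(text)


def read_activity_log(
    path: str | os.PathLike | io.TextIOBase, registry: ActivityRegistry
) -> list[ActivityEvent]:
    """Read an activity-log CSV into validated events, in file order.

    Missing ``order_index`` information is synthesised from row order within
    each (subject, date) group.  Raises :class:`LogFormatError` naming the
    offending row for unknown activities or non-positive durations.
    """
    df = pd.read_csv(path, dtype={"subject": str, "window": str, "clock_time": str})
    missing = [c for c in ("subject", "date", "activity", "duration_min") if c not in df.columns]
    if missing:
        raise LogFormatError(f"log is missing required columns: {missing}")
    events: list[ActivityEvent] = []
    counters: dict[tuple[str, str], int] = {}
    unknown: list[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        duration = float(row.duration_min)
        if duration <= 0:
            raise LogFormatError(f"row {row_no}: non-positive duration {duration}")
        try:
            activity_id = _resolve_activity(row.activity, registry)
        except LogFormatError:
            unknown.append(str(row.activity))
            continue
        date = _dt.date.fromisoformat(str(row.date))
        clock = getattr(row, "clock_time", None)
        clock_time = _parse_time(str(clock)) if clock is not None and not pd.isna(clock) else None
        window = getattr(row, "window", None)
        window = None if window is None or pd.isna(window) else str(window)
        key = (str(row.subject), str(row.date))
        order = counters.get(key, 0)
        counters[key] = order + 1
        events.append(
            ActivityEvent(
                subject=str(row.subject),
                date=date,
                order_index=order,
                activity_id=activity_id,
                duration=duration,
                clock_time=clock_time,
                window=window,
            )
        )
    if unknown:
        raise LogFormatError(f"unknown activities in log: {sorted(set(unknown))}")
    return events


def write_activity_log(
    events: Sequence[ActivityEvent],
    path: str | os.PathLike | io.TextIOBase,
    registry: ActivityRegistry | None = None,
) -> None:
    """Write events to the canonical CSV schema (names if a registry is given)."""
    rows = []
    for ev in events:
        activity = registry.name_of(ev.activity_id) if registry is not None else ev.activity_id
        rows.append(
            {
                "subject": ev.subject,
                "date": ev.date.isoformat(),
                "clock_time": ev.clock_time.isoformat("minutes") if ev.clock_time else "",
                "window": ev.window or "",
                "activity": activity,
                "duration_min": ev.duration,
            }
        )
    pd.DataFrame(rows, columns=LOG_COLUMNS).to_csv(path, index=False)


def extract_sequences(
    events: Sequence[ActivityEvent],
    windows: PhaseWindows | None = None,
    session_mode: bool = False,
) -> list[HabitSequence]:
    """Group events into one :class:`HabitSequence` per observation window.

    In session mode each (subject, date) pair yields one sequence, labelled by
    the event's ``window`` field (default ``"session"``).  In phase mode every
    event must carry a clock time, which places it into one of the given
    day-phase windows; each non-empty (subject, date, phase) yields one
    sequence.  Events are ordered by ``order_index`` within a group.  The
    output partitions the input: every event lands in exactly one sequence.
    """
    if windows is None and not session_mode:
        raise ValueError("either pass phase windows or set session_mode=True")
    groups: dict[tuple[str, _dt.date, str], list[ActivityEvent]] = {}
    for ev in events:
        if session_mode:
            label = ev.window or "session"
        else:
            if ev.clock_time is None:
                raise ValueError(
                    f"phase mode requires a clock_time on every event "
                    f"(subject {ev.subject}, date {ev.date})"
                )
            label = windows.label_for(ev.clock_time)
        groups.setdefault((ev.subject, ev.date, label), []).append(ev)
    sequences = []
    for (subject, date, label), evs in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1].isoformat(), kv[0][2])
    ):
        evs = sorted(evs, key=lambda e: e.order_index)
        sequences.append(
            HabitSequence(
                subject=subject,
                window_label=label,
                ids=tuple(e.activity_id for e in evs),
                durations=tuple(e.duration for e in evs),
                date=date,
            )
        )
    return sequences
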