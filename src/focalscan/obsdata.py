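"""Data model and I/O for behavioural observation data.

Individuals, group rosters with membership intervals, focal-follow and scan
sessions, and dyadic observation events, together with the co-presence
exposure quantities that normalize edge weights: accumulated focal
observation hours (FAS) or scan session counts (ABS) while both members of a
dyad were resident in the group.

Timestamps are ISO-8601 strings in the CSV files; internally every time is a
plain float of seconds (membership intervals are half-open ``[entry, exit)``
and sessions are attributed to an interval by their start time).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Behaviour",
    "Method",
    "Individual",
    "GroupRoster",
    "FocalSession",
    "ScanSession",
    "ObservationEvent",
    "SchemaError",
    "ValidationError",
    "read_events",
    "write_events",
    "read_roster",
    "write_roster",
    "read_focal_sessions",
    "write_focal_sessions",
    "read_scan_sessions",
    "write_scan_sessions",
    "copresence_exposure_fas",
    "copresence_exposure_abs",
    "exposure_matrix",
    "filter_period",
]


class SchemaError(ValueError):
    """An input file does not match the expected schema."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant."""


class Behaviour(str, enum.Enum):
    GROOMING = "grooming"
    HUDDLING = "huddling"
    AGGRESSION = "aggression"


class Method(str, enum.Enum):
    FAS = "FAS"
    ABS = "ABS"


BEHAVIOURS = tuple(b.value for b in Behaviour)
METHODS = tuple(m.value for m in Method)


def parse_time(value) -> float:
    """Parse an ISO-8601 timestamp (or a bare number of seconds) to seconds."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    s = str(value).strip()
    try:
        return float(s)
    except ValueError:
        pass
    ts = pd.Timestamp(s)
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    return float((ts - pd.Timestamp(0)) / pd.Timedelta(seconds=1))


def format_time(seconds: float) -> str:
    return (pd.Timestamp(0) + pd.Timedelta(seconds=float(seconds))).isoformat()


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str  # "M" or "F"
    group_id: str
    entry_time: float
    exit_time: float | None = None  # None = still present at end of study

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValidationError(f"individual {self.id}: sex must be M or F, got {self.sex!r}")
        if self.exit_time is not None and not self.entry_time < self.exit_time:
            raise ValidationError(
                f"individual {self.id}: entry_time ({self.entry_time}) must precede "
                f"exit_time ({self.exit_time})"
            )

    def resident(self, t: float) -> bool:
        """True if the individual is a group member at time ``t`` ([entry, exit))."""
        if t < self.entry_time:
            return False
        return self.exit_time is None or t < self.exit_time


@dataclass
class GroupRoster:
    group_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self):
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            from collections import Counter

            dup = sorted(i for i, c in Counter(ids).items() if c > 1)
            raise ValidationError(f"roster {self.group_id}: duplicate individual id(s) {dup}")
        self._by_id = {m.id: m for m in self.members}

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __getitem__(self, individual_id: str) -> Individual:
        try:
            return self._by_id[individual_id]
        except KeyError:
            raise KeyError(f"unknown individual {individual_id!r} in group {self.group_id}") from None

    @property
    def ids(self) -> list[str]:
        """Member ids in lexicographic order (the canonical node order)."""
        return sorted(self._by_id)

    def resident_ids(self, t: float) -> list[str]:
        return sorted(m.id for m in self.members if m.resident(t))


@dataclass(frozen=True)
class FocalSession:
    session_id: str
    focal_id: str
    start: float
    duration: float = 600.0  # seconds; 10-min follows

    def __post_init__(self):
        if self.duration <= 0:
            raise ValidationError(f"session {self.session_id}: duration must be > 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class ScanSession:
    session_id: str
    start: float
    duration: float = 600.0
    visible_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.duration <= 0:
            raise ValidationError(f"session {self.session_id}: duration must be > 0")
        object.__setattr__(self, "visible_ids", frozenset(self.visible_ids))

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class ObservationEvent:
    timestamp: float
    behaviour: Behaviour
    actor_id: str
    recipient_id: str
    method: Method
    session_id: str

    def __post_init__(self):
        if self.actor_id == self.recipient_id:
            raise ValidationError(
                f"event in session {self.session_id}: actor and recipient are both "
                f"{self.actor_id!r}"
            )


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["timestamp", "behaviour", "actor", "recipient", "method", "session_id"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_events(path) -> list[ObservationEvent]:
    """Read an observation-event log (CSV) into a list of events.

    Expected header: timestamp, behaviour, actor, recipient, method, session_id.
    Unknown behaviours/methods and self-interactions raise with the offending
    row number (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, _EVENT_COLUMNS, path)
    events: list[ObservationEvent] = []
    for row_num, row in enumerate(df.itertuples(index=False), start=1):
        if row.behaviour not in BEHAVIOURS:
            raise SchemaError(
                f"{path}: row {row_num}: unknown behaviour {row.behaviour!r} "
                f"(expected one of {BEHAVIOURS})"
            )
        if row.method not in METHODS:
            raise SchemaError(
                f"{path}: row {row_num}: unknown method {row.method!r} "
                f"(expected one of {METHODS})"
            )
        if row.actor == row.recipient:
            raise ValidationError(f"{path}: row {row_num}: actor equals recipient ({row.actor!r})")
        events.append(
            ObservationEvent(
                timestamp=parse_time(row.timestamp),
                behaviour=Behaviour(row.behaviour),
                actor_id=str(row.actor),
                recipient_id=str(row.recipient),
                method=Method(row.method),
                session_id=str(row.session_id),
            )
        )
    return events


def write_events(events, path) -> None:
    pd.DataFrame(
        {
            "timestamp": [format_time(e.timestamp) for e in events],
            "behaviour": [e.behaviour.value for e in events],
            "actor": [e.actor_id for e in events],
            "recipient": [e.recipient_id for e in events],
            "method": [e.method.value for e in events],
            "session_id": [e.session_id for e in events],
        }
    ).to_csv(path, index=False)


def read_roster(path) -> GroupRoster:
    """Read a group roster (CSV: id, sex, group_id, entry_time, exit_time)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["id", "sex", "group_id", "entry_time"], path)
    members = []
    group_ids = set()
    for row in df.itertuples(index=False):
        exit_raw = getattr(row, "exit_time", None)
        has_exit = exit_raw is not None and not (isinstance(exit_raw, float) and math.isnan(exit_raw))
        has_exit = has_exit and str(exit_raw).strip() not in ("", "nan")
        members.append(
            Individual(
                id=str(row.id),
                sex=str(row.sex),
                group_id=str(row.group_id),
                entry_time=parse_time(row.entry_time),
                exit_time=parse_time(exit_raw) if has_exit else None,
            )
        )
        group_ids.add(str(row.group_id))
    if len(group_ids) > 1:
        raise SchemaError(f"{path}: roster mixes group ids {sorted(group_ids)}")
    return GroupRoster(group_id=group_ids.pop() if group_ids else "", members=members)


def write_roster(roster: GroupRoster, path) -> None:
    pd.DataFrame(
        {
            "id": [m.id for m in roster.members],
            "sex": [m.sex for m in roster.members],
            "group_id": [m.group_id for m in roster.members],
            "entry_time": [format_time(m.entry_time) for m in roster.members],
            "exit_time": ["" if m.exit_time is None else format_time(m.exit_time) for m in roster.members],
        }
    ).to_csv(path, index=False)


def read_focal_sessions(path) -> list[FocalSession]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["session_id", "focal_id", "start", "duration"], path)
    return [
        FocalSession(
            session_id=str(r.session_id),
            focal_id=str(r.focal_id),
            start=parse_time(r.start),
            duration=float(r.duration),
        )
        for r in df.itertuples(index=False)
    ]


def write_focal_sessions(sessions, path) -> None:
    pd.DataFrame(
        {
            "session_id": [s.session_id for s in sessions],
            "focal_id": [s.focal_id for s in sessions],
            "start": [format_time(s.start) for s in sessions],
            "duration": [s.duration for s in sessions],
        }
    ).to_csv(path, index=False)


def read_scan_sessions(path) -> list[ScanSession]:
    """Read scan sessions; ``visible_ids`` is a ';'-separated id list."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["session_id", "start", "duration", "visible_ids"], path)
    sessions = []
    for r in df.itertuples(index=False):
        raw = "" if (isinstance(r.visible_ids, float) and math.isnan(r.visible_ids)) else str(r.visible_ids)
        visible = frozenset(x for x in raw.split(";") if x)
        sessions.append(
            ScanSession(
                session_id=str(r.session_id),
                start=parse_time(r.start),
                duration=float(r.duration),
                visible_ids=visible,
            )
        )
    return sessions


def write_scan_sessions(sessions, path) -> None:
    pd.DataFrame(
        {
            "session_id": [s.session_id for s in sessions],
            "start": [format_time(s.start) for s in sessions],
            "duration": [s.duration for s in sessions],
            "visible_ids": [";".join(sorted(s.visible_ids)) for s in sessions],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Co-presence exposure
# ---------------------------------------------------------------------------

def _check_ids(roster: GroupRoster, *ids: str) -> None:
    for i in ids:
        if i not in roster:
            raise KeyError(f"unknown individual {i!r} in group {roster.group_id}")


def copresence_exposure_fas(
    roster: GroupRoster,
    sessions: list[FocalSession],
    i: str,
    j: str,
    mode: str = "observation_hours",
) -> float:
    """FAS exposure of dyad (i, j): co-resident observation effort in hours.

    ``mode="observation_hours"`` (default) accumulates the duration of every
    focal follow whose start falls while both i and j are resident, so FAS
    edge weights are events per observation-hour — parallel to ABS events per
    session. ``mode="calendar_hours"`` instead returns the calendar overlap
    of the two residency intervals clipped to the observed session span.
    """
    if i == j:
        raise ValidationError("exposure is defined for distinct individuals")
    _check_ids(roster, i, j)
    a, b = roster[i], roster[j]
    if mode == "observation_hours":
        total = sum(s.duration for s in sessions if a.resident(s.start) and b.resident(s.start))
        return total / 3600.0
    if mode == "calendar_hours":
        if not sessions:
            return 0.0
        lo = min(s.start for s in sessions)
        hi = max(s.end for s in sessions)
        start = max(a.entry_time, b.entry_time, lo)
        end = min(
            a.exit_time if a.exit_time is not None else hi,
            b.exit_time if b.exit_time is not None else hi,
            hi,
        )
        return max(0.0, end - start) / 3600.0
    raise ValueError(f"unknown FAS exposure mode {mode!r}")


def copresence_exposure_abs(
    roster: GroupRoster,
    sessions: list[ScanSession],
    i: str,
    j: str,
) -> int:
    """ABS exposure of dyad (i, j): number of scan sessions conducted while
    both were resident in the group (residency, not per-session visibility)."""
    if i == j:
        raise ValidationError("exposure is defined for distinct individuals")
    _check_ids(roster, i, j)
    a, b = roster[i], roster[j]
    return sum(1 for s in sessions if a.resident(s.start) and b.resident(s.start))


def exposure_matrix(roster: GroupRoster, sessions, method: Method | str, mode: str = "observation_hours"):
    """Dyadic exposure for every ordered pair of roster members.

    Returns ``(node_ids, E)`` with ``node_ids`` in lexicographic order and
    ``E[i, j]`` the FAS co-resident observation hours or ABS co-resident
    session count (diagonal 0). Vectorized over sessions: a session
    contributes to every dyad resident at its start.
    """
    method = Method(method)
    ids = roster.ids
    n = len(ids)
    E = np.zeros((n, n))
    starts = np.array([s.start for s in sessions], dtype=float)
    if starts.size:
        entry = np.array([roster[i].entry_time for i in ids])
        exit_ = np.array(
            [np.inf if roster[i].exit_time is None else roster[i].exit_time for i in ids]
        )
        resident = (starts[:, None] >= entry[None, :]) & (starts[:, None] < exit_[None, :])
        if method is Method.FAS and mode == "observation_hours":
            weights = np.array([s.duration for s in sessions]) / 3600.0
        elif method is Method.ABS:
            weights = np.ones(len(sessions))
        elif method is Method.FAS and mode == "calendar_hours":
            # calendar overlap does not decompose over sessions; fall back per dyad
            for a in range(n):
                for b in range(a + 1, n):
                    E[a, b] = E[b, a] = copresence_exposure_fas(
                        roster, sessions, ids[a], ids[b], mode="calendar_hours"
                    )
            return ids, E
        else:
            raise ValueError(f"unknown exposure mode {mode!r}")
        R = resident.astype(float)
        E = (R * weights[:, None]).T @ R  # sum_s w_s * resident[s,i] * resident[s,j]
    np.fill_diagonal(E, 0.0)
    return ids, E


def filter_period(events, start: float, end: float):
    """Events with ``start <= timestamp < end`` (half-open)."""
    if start > end:
        raise ValueError("filter_period: start must be <= end")
    return [e for e in events if start <= e.timestamp < end]
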