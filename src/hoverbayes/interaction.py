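"""Hover-event parsing, validity filtering, dwell times and bigram transitions.

Eight screen locations (buttons) are tracked: the seven tree nodes plus the
question button Q.  A hover is an explicit reveal — the participant moved the
cursor onto the button, which uncovered the value beneath — so enter/exit
timestamps delimit genuine inspection episodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    EmptyGroupError,
    MalformedLogError,
    SchemaError,
    UndefinedDwellError,
)

__all__ = [
    "AOIS",
    "TRANSITION_PAIRS",
    "HoverEvent",
    "HoverSequence",
    "TransitionTable",
    "ValidityReport",
    "parse_event_log",
    "validity_filter",
    "dwell_percentages",
    "bigram_transitions",
    "pool_group",
    "write_event_log",
]

#: The 8 AOI codes, in canonical order.
AOIS = ("T", "F", "nF", "FA", "FnA", "nFA", "nFnA", "Q")

#: The 56 ordered AOI pairs (8 x 7, self-pairs excluded), canonical order.
TRANSITION_PAIRS = tuple((a, b) for a in AOIS for b in AOIS if a != b)

_EVENT_COLUMNS = ("participant_id", "aoi", "enter_ms", "exit_ms")


@dataclass(frozen=True)
class HoverEvent:
    """One hover episode: the cursor entered an AOI at ``enter_ms`` and left
    at ``exit_ms`` (half-open interval, milliseconds since task start)."""

    participant_id: str
    aoi: str
    enter_ms: int
    exit_ms: int

    def __post_init__(self) -> None:
        if self.aoi not in AOIS:
            raise SchemaError(f"unknown AOI code {self.aoi!r}")
        if self.enter_ms < 0:
            raise MalformedLogError("enter_ms must be non-negative")
        if self.exit_ms <= self.enter_ms:
            raise MalformedLogError("exit_ms must exceed enter_ms")

    @property
    def duration_ms(self) -> int:
        return self.exit_ms - self.enter_ms


@dataclass(frozen=True)
class HoverSequence:
    """All hover events of one participant, sorted by enter time.

    ``visits`` is the derived AOI visit sequence with immediate repeats
    collapsed (re-hovering the same button with no other button in between
    counts as a single visit), which makes the 56-pair transition space
    exhaustive.
    """

    participant_id: str
    events: tuple[HoverEvent, ...]

    def __post_init__(self) -> None:
        prev_exit = None
        for ev in self.events:
            if ev.participant_id != self.participant_id:
                raise MalformedLogError("event participant mismatch")
            if prev_exit is not None and ev.enter_ms < prev_exit:
                raise MalformedLogError(
                    f"overlapping hover events for {self.participant_id}"
                )
            prev_exit = ev.exit_ms

    @property
    def visits(self) -> tuple[str, ...]:
        out: list[str] = []
        for ev in self.events:
            if not out or out[-1] != ev.aoi:
                out.append(ev.aoi)
        return tuple(out)

    def dwell_ms(self) -> dict[str, int]:
        """Total hover duration per AOI (all events, pre-collapse)."""
        totals = dict.fromkeys(AOIS, 0)
        for ev in self.events:
            totals[ev.aoi] += ev.duration_ms
        return totals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (ev.participant_id, ev.aoi, ev.enter_ms, ev.exit_ms)
                for ev in self.events
            ],
            columns=list(_EVENT_COLUMNS),
        )


def parse_event_log(
    records: pd.DataFrame | str | Path,
    *,
    min_duration_ms: int = 0,
    sep: str = ",",
) -> list[HoverSequence]:
    """Parse a tabular hover log into one time-sorted sequence per participant.

    ``records`` is a DataFrame or a path to a delimited text file with columns
    participant_id, aoi, enter_ms, exit_ms.  Hovers shorter than
    ``min_duration_ms`` are dropped (default: keep everything).  Sequences are
    returned sorted by participant id.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.read_csv(records, sep=sep, dtype={"participant_id": str})
    missing = set(_EVENT_COLUMNS) - set(records.columns)
    if missing:
        raise SchemaError(f"event log missing columns: {sorted(missing)}")
    bad = set(records["aoi"].unique()) - set(AOIS)
    if bad:
        raise SchemaError(f"unknown AOI codes in event log: {sorted(bad)}")
    sequences = []
    for pid, grp in records.groupby("participant_id", sort=True):
        grp = grp.sort_values("enter_ms", kind="mergesort")
        events = [
            HoverEvent(str(pid), row.aoi, int(row.enter_ms), int(row.exit_ms))
            for row in grp.itertuples(index=False)
            if int(row.exit_ms) - int(row.enter_ms) >= min_duration_ms
        ]
        sequences.append(HoverSequence(str(pid), tuple(events)))
    return sequences


def write_event_log(
    sequences: Iterable[HoverSequence], path: str | Path, *, sep: str = ","
) -> None:
    """Serialize sequences back to the delimited on-disk format (lossless)."""
    frames = [seq.to_frame() for seq in sequences]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(_EVENT_COLUMNS))
    )
    df.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class ValidityReport:
    participant_id: str
    included: bool
    reasons: tuple[str, ...]


def validity_filter(seq: HoverSequence, meta: Mapping | None = None) -> ValidityReport:
    """Apply the participant exclusion rules.

    A participant is excluded if (a) an active ad-blocker was not disabled
    (``meta['adblocker_disabled']`` falsy), (b) the question button Q was never
    hovered, or (c) fewer than two distinct non-Q locations were hovered.
    """
    reasons: list[str] = []
    if meta is not None and not bool(meta.get("adblocker_disabled", True)):
        reasons.append("adblocker_active")
    visited = {ev.aoi for ev in seq.events}
    if "Q" not in visited:
        reasons.append("question_never_viewed")
    if len(visited - {"Q"}) < 2:
        reasons.append("fewer_than_two_info_views")
    return ValidityReport(seq.participant_id, not reasons, tuple(reasons))


def dwell_percentages(seq: HoverSequence) -> dict[str, float]:
    """Hover time on each AOI as a percentage of total hover time.

    Returns a value for each of the 8 AOIs (zeros for unvisited ones);
    percentages sum to 100.
    """
    totals = seq.dwell_ms()
    grand = sum(totals.values())
    if grand <= 0:
        raise UndefinedDwellError(
            f"participant {seq.participant_id} has zero total hover time"
        )
    return {aoi: 100.0 * t / grand for aoi, t in totals.items()}


@dataclass(frozen=True)
class TransitionTable:
    """Counts over the 56 ordered AOI pairs, for one participant or a pooled group."""

    scope: str  # "participant" | "group"
    counts: Mapping[tuple[str, str], int]
    label: str | None = None

    def __post_init__(self) -> None:
        if self.scope not in ("participant", "group"):
            raise ValueError("scope must be 'participant' or 'group'")
        if set(self.counts) != set(TRANSITION_PAIRS):
            raise ValueError("counts must cover exactly the 56 ordered AOI pairs")
        for pair, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"count for {pair} must be a non-negative integer")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def normalized(self) -> dict[tuple[str, str], float]:
        """Relative frequencies; all-zero when the table is empty."""
        tot = self.total
        if tot == 0:
            return {pair: 0.0 for pair in TRANSITION_PAIRS}
        return {pair: self.counts[pair] / tot for pair in TRANSITION_PAIRS}

    def as_array(self):
        import numpy as np

        return np.array([self.counts[p] for p in TRANSITION_PAIRS], dtype=float)

    @classmethod
    def from_array(cls, values, scope: str = "group", label: str | None = None):
        counts = {p: int(v) for p, v in zip(TRANSITION_PAIRS, values)}
        return cls(scope, counts, label)

    def to_json(self) -> str:
        """Bit-stable JSON export with fixed key ordering for diffing."""
        payload = {
            "scope": self.scope,
            "label": self.label,
            "total": self.total,
            "counts": {f"{a}->{b}": int(self.counts[(a, b)]) for a, b in TRANSITION_PAIRS},
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TransitionTable":
        payload = json.loads(text)
        counts = {}
        for key, value in payload["counts"].items():
            a, b = key.split("->")
            counts[(a, b)] = int(value)
        return cls(payload["scope"], counts, payload.get("label"))


def bigram_transitions(seq: HoverSequence) -> TransitionTable:
    """Count consecutive ordered AOI pairs in the collapsed visit sequence.

    Self-pairs are impossible by construction; an empty or singleton sequence
    yields an all-zero table.
    """
    counts = {pair: 0 for pair in TRANSITION_PAIRS}
    visits = seq.visits
    for a, b in zip(visits, visits[1:]):
        counts[(a, b)] += 1
    return TransitionTable("participant", counts, label=seq.participant_id)


def pool_group(
    tables: Sequence[TransitionTable], group_label: str | None = None
) -> TransitionTable:
    """Sum participant tables element-wise into one group-scope table."""
    tables = list(tables)
    if not tables:
        raise EmptyGroupError("cannot pool an empty group")
    for t in tables:
        if t.scope != "participant":
            raise ValueError("pool_group expects participant-scope tables")
    counts = {pair: 0 for pair in TRANSITION_PAIRS}
    for t in tables:
        for pair in TRANSITION_PAIRS:
            counts[pair] += int(t.counts[pair])
    return TransitionTable("group", counts, label=group_label)
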