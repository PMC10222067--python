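"""Domain types and IO for smart-bed behavior logs.

A behavior log is an ordered sequence of records ``(type, time, duration)``
where ``type`` is either a bed-region identifier or the sentinel ``moving``.
A located record means the patient settled at a position inside that region;
a ``moving`` record is a transit between two located states.  The bed itself
is split into a fixed number of longitudinal sectors ("regions", "areas"),
each served by a pair of sensor nodes.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

MOVING = "moving"

__all__ = [
    "MOVING",
    "BedLayout",
    "BehaviorRecord",
    "BehaviorLog",
    "ResolvedMove",
    "LogValidationError",
    "LogParseError",
    "default_layout",
    "read_layout",
    "read_log",
    "write_log",
    "resolve_moves",
]


class LogValidationError(ValueError):
    """A record violates the behavior-log contract (vocabulary, ordering)."""


class LogParseError(ValueError):
    """A line of an on-disk log could not be parsed."""


# --------------------------------------------------------------------------
# Bed layout
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BedLayout:
    """Static description of the bed: regions, sensor nodes, node roles.

    Parameters
    ----------
    region_ids
        Ordered region identifiers, e.g. ``["r1", ..., "r5"]``.  Region
        identifiers are 1-based in their names but indexed 0-based
        internally (``region_index``).
    node_ids
        Ordered sensor-node identifiers, e.g. ``["n1", ..., "n10"]``.
    node_to_region
        Mapping node id -> region id; every node belongs to exactly one
        region and every region has at least one node.
    node_sensor
        Mapping node id -> sensor-role label (pressure, infrared, ...).
    """

    region_ids: tuple[str, ...]
    node_ids: tuple[str, ...]
    node_to_region: dict[str, str]
    node_sensor: dict[str, str]

    def __post_init__(self) -> None:
        if not self.region_ids:
            raise ValueError("layout needs at least one region")
        if set(self.node_to_region) != set(self.node_ids):
            raise ValueError("node_to_region must cover exactly node_ids")
        unknown = set(self.node_to_region.values()) - set(self.region_ids)
        if unknown:
            raise ValueError(f"nodes mapped to unknown regions: {sorted(unknown)}")
        empty = set(self.region_ids) - set(self.node_to_region.values())
        if empty:
            raise ValueError(f"regions without nodes: {sorted(empty)}")

    @property
    def region_count(self) -> int:
        return len(self.region_ids)

    @property
    def node_count(self) -> int:
        return len(self.node_ids)

    def region_index(self, region_id: str) -> int:
        return self.region_ids.index(region_id)

    def region_nodes(self, region_id: str) -> list[str]:
        return [n for n in self.node_ids if self.node_to_region[n] == region_id]


def default_layout() -> BedLayout:
    """The shipped 5-sector / 10-node layout with the standard sensor roles."""
    with resources.files("bedmap.data").joinpath("default_layout.yaml").open() as fh:
        return _layout_from_mapping(yaml.safe_load(fh))


def read_layout(path: str | Path) -> BedLayout:
    with open(path) as fh:
        return _layout_from_mapping(yaml.safe_load(fh))


def _layout_from_mapping(doc: dict) -> BedLayout:
    regions = tuple(doc["regions"])
    nodes = doc["nodes"]
    return BedLayout(
        region_ids=regions,
        node_ids=tuple(nodes),
        node_to_region={n: spec["region"] for n, spec in nodes.items()},
        node_sensor={n: spec["sensor"] for n, spec in nodes.items()},
    )


# --------------------------------------------------------------------------
# Records and logs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorRecord:
    """One logged event: a located state or a transit.

    ``record_type`` is a region identifier or :data:`MOVING`; ``time`` is
    session-relative seconds; ``duration`` is the dwell (located) or transit
    (moving) length in seconds.
    """

    record_type: str
    time: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise LogValidationError(f"negative time {self.time}")
        if self.duration < 0:
            raise LogValidationError(f"negative duration {self.duration}")

    @property
    def is_moving(self) -> bool:
        return self.record_type == MOVING


@dataclass(frozen=True)
class ResolvedMove:
    """A MOVING record resolved against its located neighbours."""

    origin: str
    destination: str
    time: float
    duration: float

    @property
    def within_region(self) -> bool:
        return self.origin == self.destination


@dataclass
class BehaviorLog:
    """A validated, time-ordered sequence of behavior records."""

    records: list[BehaviorRecord]
    layout: BedLayout
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        regions = set(self.layout.region_ids)
        prev_time = -float("inf")
        prev_moving = False
        for i, rec in enumerate(self.records):
            if not rec.is_moving and rec.record_type not in regions:
                raise LogValidationError(
                    f"record {i}: unknown region {rec.record_type!r}"
                )
            if rec.time < prev_time:
                raise LogValidationError(
                    f"record {i}: time regression {rec.time} < {prev_time}"
                )
            if rec.is_moving and prev_moving:
                raise LogValidationError(
                    f"record {i}: two consecutive moving records"
                )
            prev_time = rec.time
            prev_moving = rec.is_moving

    def __len__(self) -> int:
        return len(self.records)

    @property
    def start_time(self) -> float:
        return self.records[0].time if self.records else 0.0

    @property
    def end_time(self) -> float:
        """End of the last record's span."""
        if not self.records:
            return 0.0
        last = self.records[-1]
        return last.time + last.duration

    def with_recomputed_dwell(self) -> "BehaviorLog":
        """Return a copy where each located record's duration is the dwell
        until the next record (the last keeps its stored duration)."""
        recs = list(self.records)
        for i in range(len(recs) - 1):
            if not recs[i].is_moving:
                recs[i] = replace(recs[i], duration=recs[i + 1].time - recs[i].time)
        return BehaviorLog(recs, self.layout, self.session_id)


# --------------------------------------------------------------------------
# IO — canonical CSV dialect, plus JSONL
# --------------------------------------------------------------------------

_HEADER = ["session_id", "type", "time_s", "duration_s"]


def _fmt(x: float) -> str:
    # canonical number formatting so write∘read is byte-stable
    return f"{float(x):.6f}".rstrip("0").rstrip(".")


def read_log(path: str | Path, layout: BedLayout | None = None) -> BehaviorLog:
    """Read a behavior log from CSV (header ``session_id,type,time_s,duration_s``)
    or JSONL (one record object per line, same keys).

    Located records whose duration is absent get it recomputed as the dwell
    until the next record.  Unknown regions and time regressions raise.
    """
    layout = layout or default_layout()
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".json"}:
        rows = _read_jsonl(path)
    else:
        rows = _read_csv(path)

    session_id = rows[0]["session_id"] if rows else "session"
    records = []
    missing = []
    for lineno, row in rows_with_lineno(rows):
        try:
            raw_dur = row.get("duration_s")
            has_dur = raw_dur not in (None, "")
            rec = BehaviorRecord(
                record_type=str(row["type"]),
                time=float(row["time_s"]),
                duration=float(raw_dur) if has_dur else 0.0,
            )
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, LogValidationError):
                raise
            raise LogParseError(f"{path}: line {lineno}: {exc}") from exc
        missing.append(not has_dur)
        records.append(rec)
    # absent located durations are the dwell until the next record
    for i, lacks in enumerate(missing):
        if lacks and not records[i].is_moving and i + 1 < len(records):
            records[i] = replace(records[i], duration=records[i + 1].time - records[i].time)
    return BehaviorLog(records, layout, session_id)


def rows_with_lineno(rows: list[dict]) -> Iterable[tuple[int, dict]]:
    # data lines start at 2 (after the header) for CSV; close enough for JSONL
    return ((i + 2, row) for i, row in enumerate(rows))


def _read_csv(path: Path) -> list[dict]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != _HEADER:
            raise LogParseError(
                f"{path}: line 1: expected header {','.join(_HEADER)!r}, "
                f"got {reader.fieldnames}"
            )
        return list(reader)


def _read_jsonl(path: Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise LogParseError(f"{path}: line {lineno}: {exc}") from exc
    return rows


def write_log(log: BehaviorLog, path: str | Path) -> None:
    """Write a log in the canonical CSV dialect (``read_log`` inverts it)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for rec in log.records:
            writer.writerow(
                [log.session_id, rec.record_type, _fmt(rec.time), _fmt(rec.duration)]
            )


# --------------------------------------------------------------------------
# Move resolution
# --------------------------------------------------------------------------

def resolve_moves(log: BehaviorLog) -> list[ResolvedMove]:
    """Resolve every interior MOVING record to (origin, destination).

    The patient does not remain anywhere during a transit, so a MOVING
    record's endpoints are the located records flanking it.  Boundary MOVING
    records (no located record before or after) are dropped with a warning.
    Origin == destination is permitted (a within-region move) and flagged via
    :attr:`ResolvedMove.within_region`.
    """
    moves: list[ResolvedMove] = []
    dropped = 0
    for i, rec in enumerate(log.records):
        if not rec.is_moving:
            continue
        if i == 0 or i == len(log.records) - 1:
            dropped += 1
            continue
        prev = log.records[i - 1]
        nxt = log.records[i + 1]
        # log invariants forbid adjacent MOVING records, so both are located
        moves.append(ResolvedMove(prev.record_type, nxt.record_type, rec.time, rec.duration))
    if dropped:
        warnings.warn(
            f"dropped {dropped} boundary moving record(s) without located endpoints",
            stacklevel=2,
        )
    return moves
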