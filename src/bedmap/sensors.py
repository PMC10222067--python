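"""Sensor-side utilities: distance-threshold grouping and range-check alerts.

``group_sensors`` clusters pressure sensors whose pairwise distance falls
below a threshold.  As literally written, the scan-per-seed procedure
produces overlapping groups (every seed gets its own group containing all
of its near neighbours); ``dedupe=False`` preserves those overlap
semantics, while the default ``dedupe=True`` converts the same closeness
relation into connected components so each sensor lands in exactly one
group.

``range_alert`` partitions sensor readings into forwarded (in range,
inclusive bounds) and alerted (out of range) streams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SensorPosition",
    "SensorRange",
    "Alert",
    "group_sensors",
    "range_alert",
]


@dataclass(frozen=True)
class SensorPosition:
    sensor_id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for {self.sensor_id}")


@dataclass(frozen=True)
class SensorRange:
    sensor_id: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"{self.sensor_id}: low > high")


@dataclass(frozen=True)
class Alert:
    sensor_id: str
    value: float
    time: float


def _distance(a: SensorPosition, b: SensorPosition, metric: str) -> float:
    if metric == "euclidean":
        return float(np.hypot(a.x - b.x, a.y - b.y))
    if metric == "manhattan":
        return abs(a.x - b.x) + abs(a.y - b.y)
    raise ValueError(f"unknown metric {metric!r}")


def group_sensors(
    positions: Sequence[SensorPosition],
    threshold: float,
    dedupe: bool = True,
    metric: str = "euclidean",
) -> list[list[str]]:
    """Group sensors whose distance is strictly below ``threshold``.

    ``dedupe=True`` (default): connected components of the closeness graph —
    a partition of the sensor ids.  ``dedupe=False``: one group per seed
    sensor holding the seed plus every *other* sensor closer than the
    threshold (overlapping groups, the literal scan semantics; the seed is
    excluded from its own neighbour scan).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ids = [p.sensor_id for p in positions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sensor_ids")

    n = len(positions)
    close = [
        [
            i != j and _distance(positions[i], positions[j], metric) < threshold
            for j in range(n)
        ]
        for i in range(n)
    ]

    if not dedupe:
        return [
            [ids[i]] + [ids[j] for j in range(n) if close[i][j]] for i in range(n)
        ]

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if close[i][j]:
                parent[find(j)] = find(i)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ids[i])
    return [groups[r] for r in sorted(groups, key=lambda r: min(groups[r]))]


def range_alert(
    readings: Sequence[tuple[str, float, float]],
    ranges: Mapping[str, SensorRange],
) -> tuple[list[tuple[str, float, float]], list[Alert]]:
    """Split readings ``(sensor_id, value, time)`` into forwarded in-range
    readings and alerts.  Bounds are inclusive; the partition is exhaustive
    and exclusive.  Unknown sensors raise."""
    forwarded = []
    alerts = []
    for sensor_id, value, time in readings:
        if sensor_id not in ranges:
            raise KeyError(f"no range configured for sensor {sensor_id!r}")
        rng = ranges[sensor_id]
        if rng.low <= value <= rng.high:
            forwarded.append((sensor_id, value, time))
        else:
            alerts.append(Alert(sensor_id, value, time))
    return forwarded, alerts
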