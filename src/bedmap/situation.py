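"""Cluster-to-situation mapping, movement metrics, and anomaly flagging.

Phase-2 clusters are abstract; care staff need them named.  Each cluster is
summarised by (a) its *self-loop composition* — what fraction of the
cluster's total edge weight sits on each phase-1 label's self-loop, stable
occupancy of one spatial pattern — (b) the fraction of weight off the
diagonal, actual transitions between patterns, and (c) a 24-bin hour-of-day
histogram of when its intervals occur.  A declarative, ordered rule list
maps summaries to scenario names (night rest, movement onset, ...); the
first matching rule wins and unmatched clusters stay "unmapped".

Movement metrics quantify restlessness directly from the log: the
percentage of each tumbling window spent in the MOVING state.  Windows
strictly above a configurable attention threshold (default 30%) are flagged
as needing staff attention.

Anomaly flagging scores a new transition graph by its Frobenius distance to
the nearest phase-2 centroid; a graph farther than ``mean + k_sigma * sd``
of that cluster's training distances differs from every previously known
movement pattern and is reported as anomalous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .logmodel import BehaviorLog
from .stcluster import GraphClusterModel, TransitionGraph

__all__ = [
    "ClusterSummary",
    "SituationRule",
    "SituationMap",
    "MovementMetrics",
    "summarize_clusters",
    "map_to_situations",
    "load_rules",
    "default_rules",
    "moving_fraction",
    "attention_flags",
    "detect_anomaly",
]

NIGHT_HOURS = frozenset(list(range(20, 24)) + list(range(0, 8)))


# --------------------------------------------------------------------------
# Cluster summaries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSummary:
    """Composition and timing profile of one phase-2 cluster."""

    cluster_label: int
    selfloop_composition: dict[int, float]   # phase-1 label -> weight fraction
    offdiag_fraction: float
    temporal_histogram: np.ndarray           # 24 hour-of-day bins
    centroid_matrix: np.ndarray
    graph_count: int

    @property
    def dominant_selfloop(self) -> tuple[int, float]:
        """(phase-1 label, fraction) of the heaviest self-loop."""
        label = min(
            self.selfloop_composition,
            key=lambda k: (-self.selfloop_composition[k], k),
        )
        return label, self.selfloop_composition[label]

    def hour_fraction(self, hours: Sequence[int]) -> float:
        total = self.temporal_histogram.sum()
        if total == 0:
            return 0.0
        return float(self.temporal_histogram[list(hours)].sum() / total)


def summarize_clusters(
    model2: GraphClusterModel,
    graphs: Sequence[TransitionGraph],
    timestamps: Sequence[float] | None = None,
) -> list[ClusterSummary]:
    """Per phase-2 cluster: self-loop composition, off-diagonal fraction,
    hour-of-day histogram and centroid matrix.

    ``timestamps`` are per-graph interval start times in session seconds
    (hour of day = ``(t // 3600) % 24``); they default to the graphs' own
    start times.
    """
    if timestamps is None:
        timestamps = [g.start_time for g in graphs]
    if len(timestamps) != len(graphs) or len(graphs) != len(model2.assignments):
        raise ValueError("graphs, timestamps and assignments lengths must match")

    K1 = graphs[0].adjacency.shape[0]
    summaries = []
    for label in range(1, model2.K2 + 1):
        idx = [i for i, a in enumerate(model2.assignments) if a == label]
        total = np.zeros((K1, K1), dtype=float)
        hist = np.zeros(24, dtype=int)
        for i in idx:
            total += graphs[i].adjacency
            hist[int(timestamps[i] // 3600) % 24] += 1
        weight = total.sum()
        diag = np.diag(total)
        if weight > 0:
            comp = {j + 1: float(diag[j] / weight) for j in range(K1)}
            offdiag = float((weight - diag.sum()) / weight)
        else:
            comp = {j + 1: 0.0 for j in range(K1)}
            offdiag = 0.0
        summaries.append(
            ClusterSummary(
                cluster_label=label,
                selfloop_composition=comp,
                offdiag_fraction=offdiag,
                temporal_histogram=hist,
                centroid_matrix=model2.centroid_matrices[label - 1],
                graph_count=len(idx),
            )
        )
    return summaries


# --------------------------------------------------------------------------
# Rule-driven scenario mapping
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SituationRule:
    """One declarative predicate over a ClusterSummary.

    All stated conditions must hold; the first matching rule in the list
    assigns its scenario.  Conditions:

    ``offdiag_min`` / ``offdiag_max``
        Bounds on the off-diagonal weight fraction.
    ``dominant_selfloop_label``
        The heaviest self-loop must be on this phase-1 label.
    ``dominant_selfloop_min``
        The heaviest self-loop must carry at least this weight fraction.
    ``night_fraction_min`` / ``day_fraction_min``
        Minimum fraction of the cluster's intervals falling in night/day
        hour bins.
    """

    scenario: str
    offdiag_min: float | None = None
    offdiag_max: float | None = None
    dominant_selfloop_label: int | None = None
    dominant_selfloop_min: float | None = None
    night_fraction_min: float | None = None
    day_fraction_min: float | None = None
    night_hours: frozenset[int] = NIGHT_HOURS

    def matches(self, s: ClusterSummary) -> bool:
        dom_label, dom_frac = s.dominant_selfloop
        night = s.hour_fraction(sorted(self.night_hours))
        checks = [
            self.offdiag_min is None or s.offdiag_fraction >= self.offdiag_min,
            self.offdiag_max is None or s.offdiag_fraction <= self.offdiag_max,
            self.dominant_selfloop_label is None
            or dom_label == self.dominant_selfloop_label,
            self.dominant_selfloop_min is None or dom_frac >= self.dominant_selfloop_min,
            self.night_fraction_min is None or night >= self.night_fraction_min,
            self.day_fraction_min is None or (1.0 - night) >= self.day_fraction_min,
        ]
        return all(checks)


@dataclass(frozen=True)
class SituationMap:
    """Phase-2 label -> scenario name, with the rule set used."""

    entries: dict[int, str]
    rationale: dict[int, str]
    rules: tuple[SituationRule, ...]


def map_to_situations(
    summaries: Sequence[ClusterSummary], rules: Sequence[SituationRule]
) -> SituationMap:
    """First-matching-rule scenario assignment; unmatched -> "unmapped"."""
    entries: dict[int, str] = {}
    rationale: dict[int, str] = {}
    for s in summaries:
        entries[s.cluster_label] = "unmapped"
        rationale[s.cluster_label] = "no rule matched"
        for rule in rules:
            if rule.matches(s):
                dom_label, dom_frac = s.dominant_selfloop
                entries[s.cluster_label] = rule.scenario
                rationale[s.cluster_label] = (
                    f"offdiag={s.offdiag_fraction:.2f}, dominant self-loop "
                    f"C{dom_label} ({dom_frac:.2f}), night fraction "
                    f"{s.hour_fraction(sorted(rule.night_hours)):.2f}"
                )
                break
    return SituationMap(entries, rationale, tuple(rules))


def _rules_from_doc(doc: dict) -> list[SituationRule]:
    night_hours = frozenset(doc.get("night_hours", sorted(NIGHT_HOURS)))
    rules = []
    for item in doc.get("rules", []):
        try:
            rules.append(
                SituationRule(
                    scenario=item["scenario"],
                    offdiag_min=item.get("offdiag_min"),
                    offdiag_max=item.get("offdiag_max"),
                    dominant_selfloop_label=item.get("dominant_selfloop_label"),
                    dominant_selfloop_min=item.get("dominant_selfloop_min"),
                    night_fraction_min=item.get("night_fraction_min"),
                    day_fraction_min=item.get("day_fraction_min"),
                    night_hours=night_hours,
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed situation rule {item!r}: {exc}") from exc
    return rules


def load_rules(path: str | Path) -> list[SituationRule]:
    with open(path) as fh:
        return _rules_from_doc(yaml.safe_load(fh))


def default_rules() -> list[SituationRule]:
    """The shipped rule set: transition-heavy clusters mark movement onset,
    self-loop-dominated clusters map to night/day rest scenarios."""
    with resources.files("bedmap.data").joinpath("default_rules.yaml").open() as fh:
        return _rules_from_doc(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# Movement metrics and attention flags
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MovementMetrics:
    """Per-window percentage of time spent MOVING, plus summary stats."""

    window_length_s: float
    window_starts: np.ndarray
    moving_fraction_pct: np.ndarray

    @property
    def mean_pct(self) -> float:
        return float(self.moving_fraction_pct.mean())

    @property
    def sd_pct(self) -> float:
        return float(self.moving_fraction_pct.std())

    @property
    def min_pct(self) -> float:
        return float(self.moving_fraction_pct.min())

    @property
    def max_pct(self) -> float:
        return float(self.moving_fraction_pct.max())


def moving_fraction(log: BehaviorLog, window_length_s: float = 3600.0) -> MovementMetrics:
    """Percentage of each tumbling window spent in the MOVING state.

    MOVING record spans are clipped to window boundaries, so splitting one
    MOVING record into two contiguous halves changes nothing.
    """
    if window_length_s <= 0:
        raise ValueError("window_length_s must be positive")
    t0 = log.start_time
    span = log.end_time - t0
    n_windows = max(1, int(np.ceil(span / window_length_s))) if span > 0 else 1
    starts = t0 + window_length_s * np.arange(n_windows)
    ends = starts + window_length_s

    moving = [(r.time, r.time + r.duration) for r in log.records if r.is_moving]
    frac = np.zeros(n_windows)
    for ms, me in moving:
        overlap = np.minimum(ends, me) - np.maximum(starts, ms)
        frac += np.clip(overlap, 0.0, None)
    frac = 100.0 * frac / window_length_s
    return MovementMetrics(window_length_s, starts, frac)


def attention_flags(metrics: MovementMetrics, threshold_pct: float = 30.0) -> np.ndarray:
    """Boolean per-window flags: moving fraction strictly above threshold."""
    return metrics.moving_fraction_pct > threshold_pct


# --------------------------------------------------------------------------
# Anomaly detection
# --------------------------------------------------------------------------

def detect_anomaly(
    graph: TransitionGraph,
    model2: GraphClusterModel,
    k_sigma: float = 3.0,
    abs_tol: float = 1e-9,
) -> tuple[bool, float, int]:
    """Score a transition graph against the fitted phase-2 model.

    Returns ``(is_anomalous, distance, nearest_label)`` where distance is
    the Frobenius distance to the nearest centroid matrix.  The graph is
    anomalous iff that distance exceeds ``mean + k_sigma * sd`` of the
    nearest cluster's training distances (``abs_tol`` guards degenerate
    clusters whose training spread is zero).
    """
    if graph.adjacency.shape != model2.centroid_matrices.shape[1:]:
        raise ValueError(
            f"graph shape {graph.adjacency.shape} does not match model "
            f"{model2.centroid_matrices.shape[1:]}"
        )
    flat = graph.adjacency.reshape(-1).astype(float)
    cents = model2.centroid_matrices.reshape(model2.K2, -1)
    d = np.linalg.norm(cents - flat, axis=1)
    nearest = int(np.argmin(d))
    dist = float(d[nearest])
    mean, sd = model2.distance_stats[nearest]
    threshold = mean + k_sigma * sd + abs_tol
    return dist > threshold, dist, nearest + 1
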