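"""Seeded synthetic behavior-log generator.

Real smart-bed logs from a hospital ward are piecewise stationary: long calm
stretches where the patient shifts position occasionally within one or two
bed regions, punctuated by regime changes (night rest vs. daytime activity)
and occasional agitated phases with frequent between-region movement.  The
generator emulates exactly that structure with a semi-Markov renewal model:

* while a regime is active, dwell times between position changes are
  exponential with the regime's mean;
* at each position change, with probability ``move_prob`` the patient
  transits to a region drawn from the regime's ``region_weights`` (logged as
  a MOVING record followed by a located record), otherwise the change is a
  within-region reposition (logged as a new located record in the same
  region);
* regimes switch on a wall-clock schedule, which is how day/night and
  low/high-movement phases are expressed.

Anomalous episodes (e.g. a 30-minute agitation burst at night) are produced
by splicing a window simulated from a different regime into an existing log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .logmodel import MOVING, BedLayout, BehaviorLog, BehaviorRecord, default_layout

__all__ = [
    "RegimeSpec",
    "SimulationConfig",
    "simulate_log",
    "inject_anomaly",
]


@dataclass(frozen=True)
class RegimeSpec:
    """Statistical regime governing movement behaviour for a time span.

    Parameters
    ----------
    name
        Human-readable regime label (``"night-rest"``, ``"agitated"`` ...).
    region_weights
        Probability of each region being the destination of a between-region
        move; must sum to 1 and match the layout's region count.
    mean_dwell_s
        Mean time between successive position changes (exponential).
    move_prob
        Probability that a position change is a between-region move rather
        than a within-region reposition.
    mean_move_duration_s
        Mean transit duration of a between-region move (exponential).
    """

    name: str
    region_weights: tuple[float, ...]
    mean_dwell_s: float
    move_prob: float
    mean_move_duration_s: float = 5.0

    def __post_init__(self) -> None:
        w = np.asarray(self.region_weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"region_weights must be a probability vector, got {w}")
        if self.mean_dwell_s <= 0 or self.mean_move_duration_s <= 0:
            raise ValueError("mean durations must be positive")
        if not 0.0 <= self.move_prob <= 1.0:
            raise ValueError("move_prob must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """A full simulated session: a regime schedule covering [0, total)."""

    schedule: tuple[tuple[float, float, RegimeSpec], ...]
    total_duration_s: float
    seed: int
    layout: BedLayout = field(default_factory=default_layout)
    session_id: str = "sim"

    def __post_init__(self) -> None:
        if not self.schedule:
            raise ValueError("schedule must contain at least one regime span")
        if self.total_duration_s <= 0:
            raise ValueError("total_duration_s must be positive")
        prev_end = 0.0
        for start, end, _regime in self.schedule:
            if not math.isclose(start, prev_end, abs_tol=1e-9):
                raise ValueError(
                    f"schedule must be contiguous from 0; gap/overlap at {start}"
                )
            if end <= start:
                raise ValueError("schedule spans must have positive length")
            prev_end = end
        if not math.isclose(prev_end, self.total_duration_s, abs_tol=1e-9):
            raise ValueError("schedule must cover [0, total_duration_s)")

    def regime_at(self, t: float) -> RegimeSpec:
        for start, end, regime in self.schedule:
            if start <= t < end:
                return regime
        return self.schedule[-1][2]


def _simulate_records(
    config: SimulationConfig, rng: np.random.Generator, t_offset: float = 0.0
) -> list[BehaviorRecord]:
    """Core renewal loop. Times are offset by ``t_offset`` on output."""
    layout = config.layout
    total = config.total_duration_s
    regime = config.regime_at(0.0)
    region = layout.region_ids[rng.choice(layout.region_count, p=regime.region_weights)]

    events: list[tuple[str, float, float]] = [(region, 0.0, 0.0)]
    t = 0.0
    while True:
        regime = config.regime_at(t)
        t += rng.exponential(regime.mean_dwell_s)
        if t >= total:
            break
        regime = config.regime_at(t)
        if rng.random() < regime.move_prob:
            move_dur = rng.exponential(regime.mean_move_duration_s)
            if t + move_dur >= total:
                events.append((MOVING, t, total - t))
                break
            events.append((MOVING, t, move_dur))
            t += move_dur
            region = layout.region_ids[
                rng.choice(layout.region_count, p=regime.region_weights)
            ]
            events.append((region, t, 0.0))
        else:
            events.append((region, t, 0.0))

    # located durations = dwell until the next record; last runs to the end
    records = []
    for i, (typ, time, dur) in enumerate(events):
        if typ != MOVING:
            nxt = events[i + 1][1] if i + 1 < len(events) else total
            dur = nxt - time
        records.append(BehaviorRecord(typ, time + t_offset, dur))
    return records


def simulate_log(config: SimulationConfig) -> BehaviorLog:
    """Generate a behavior log from a regime schedule.

    Deterministic for a fixed ``config.seed``; the output satisfies every
    :class:`~bedmap.logmodel.BehaviorLog` invariant.
    """
    rng = np.random.default_rng(config.seed)
    records = _simulate_records(config, rng)
    return BehaviorLog(records, config.layout, config.session_id)


def inject_anomaly(
    log: BehaviorLog,
    window: tuple[float, float],
    anomaly_regime: RegimeSpec,
    seed: int,
) -> BehaviorLog:
    """Replace the records inside ``window`` with ones drawn from
    ``anomaly_regime``, preserving all log invariants.

    A zero-length window returns the log unchanged.  The window must lie
    within the log's span.
    """
    start, end = window
    if not (log.start_time <= start <= end <= log.end_time):
        raise ValueError(
            f"window {window} outside log span "
            f"[{log.start_time}, {log.end_time}]"
        )
    if end == start:
        return BehaviorLog(list(log.records), log.layout, log.session_id)

    head = []
    for rec in log.records:
        if rec.time >= start:
            break
        dur = min(rec.duration, max(0.0, start - rec.time))
        head.append(replace(rec, duration=dur))
    tail = [rec for rec in log.records if rec.time >= end]

    seg_config = SimulationConfig(
        schedule=((0.0, end - start, anomaly_regime),),
        total_duration_s=end - start,
        seed=seed,
        layout=log.layout,
        session_id=log.session_id,
    )
    rng = np.random.default_rng(seed)
    segment = _simulate_records(seg_config, rng, t_offset=start)
    # avoid MOVING adjacency across the splice points
    if head and head[-1].is_moving and segment and segment[0].is_moving:
        segment = segment[1:]
    while segment and segment[-1].is_moving and tail and tail[0].is_moving:
        segment = segment[:-1]

    out = BehaviorLog(head + segment + tail, log.layout, log.session_id)
    return out.with_recomputed_dwell()
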