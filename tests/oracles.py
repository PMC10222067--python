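"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from first principles, by a different
route than the library (raw-point Ward costs instead of the Lance–Williams
recurrence, per-window event scans instead of vectorised accumulation),
so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def brute_ward(points: np.ndarray, K: int):
    """Naive agglomerative Ward: at every step recompute each candidate
    merge's cost directly from the raw points.

    Cluster ids follow the library convention (singletons ``0..m-1`` in
    input order, the t-th merge creates id ``m+t``); ties go to the
    lexicographically smallest id pair.  Returns (merge_history,
    assignments) with merge heights ``sqrt(2|a||b|/(|a|+|b|)) * ||ca-cb||``.
    """
    X = np.asarray(points, dtype=float)
    m = X.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(m)}
    history = []
    next_id = m
    while len(clusters) > K:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                na, nb = len(clusters[a]), len(clusters[b])
                ca = X[clusters[a]].mean(axis=0)
                cb = X[clusters[b]].mean(axis=0)
                d2 = 2.0 * na * nb / (na + nb) * float(np.sum((ca - cb) ** 2))
                if best is None or d2 < best[0] - 1e-12:
                    best = (d2, a, b)
        d2, a, b = best
        history.append((a, b, float(np.sqrt(max(d2, 0.0)))))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    assignments = np.zeros(m, dtype=int)
    order = sorted(clusters, key=lambda cid: min(clusters[cid]))
    for label, cid in enumerate(order, start=1):
        assignments[np.array(clusters[cid])] = label
    return history, assignments


def count_window_events(log, window_length_s: float) -> np.ndarray:
    """Per-window count of position-change events, by direct scan.

    A within-region change (located record repeating its region, or a
    resolved within-region move) counts 1; a between-region move counts 1
    (its mass is split 0.5/0.5 in the place vector but it is one event).
    Region changes without a MOVING record are discontinuities and count 0.
    """
    from bedmap.logmodel import MOVING

    t0 = log.records[0].time
    span = log.end_time - t0
    n = max(1, int(np.ceil(span / window_length_s)))
    counts = np.zeros(n)
    recs = log.records
    for i in range(1, len(recs)):
        rec = recs[i]
        if rec.record_type == MOVING:
            continue
        prev = recs[i - 1]
        if prev.record_type == MOVING:
            if i < 2:
                continue
            t = prev.time
        elif prev.record_type == rec.record_type:
            t = rec.time
        else:
            continue
        w = min(int((t - t0) // window_length_s), n - 1)
        counts[w] += 1
    return counts


def integrate_majority(windows, labels, a: float, b: float):
    """Majority label over [a, b) of the piecewise-constant occupancy
    defined by labelled windows; ties to the lowest label; None if no
    occupancy."""
    occ: dict[int, float] = {}
    for (ws, we), lab in zip(windows, labels):
        lo, hi = max(ws, a), min(we, b)
        if hi > lo:
            occ[int(lab)] = occ.get(int(lab), 0.0) + (hi - lo)
    if not occ:
        return None
    best_dur = max(occ.values())
    return min(l for l, d in occ.items() if d == best_dur)


def pair_transition_counts(sequence, K: int) -> np.ndarray:
    """Count consecutive-pair transitions of a 1-based label sequence."""
    A = np.zeros((K, K), dtype=int)
    for s, d in zip(sequence[:-1], sequence[1:]):
        A[s - 1, d - 1] += 1
    return A


def moving_overlap(log, start: float, end: float) -> float:
    """Total MOVING time inside [start, end), by per-record clipping."""
    from bedmap.logmodel import MOVING

    total = 0.0
    for rec in log.records:
        if rec.record_type != MOVING:
            continue
        lo = max(rec.time, start)
        hi = min(rec.time + rec.duration, end)
        if hi > lo:
            total += hi - lo
    return total


def connected_components(ids, close) -> list[set]:
    """BFS connected components of the closeness relation."""
    n = len(ids)
    seen = [False] * n
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        comp, queue = set(), [s]
        seen[s] = True
        while queue:
            i = queue.pop()
            comp.add(ids[i])
            for j in range(n):
                if close[i][j] and not seen[j]:
                    seen[j] = True
                    queue.append(j)
        comps.append(comp)
    return comps
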