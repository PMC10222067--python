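# Methods

## Behavior-log model

A behavior log is an ordered sequence of records `(type, time, duration)`.
`type` is a bed-region identifier or `moving`; `time` is session-relative
seconds (an ISO-like wall clock can be mapped in by the caller); located
records carry their dwell until the next record as `duration`, moving
records the transit length. Two invariants are enforced: times are
non-decreasing, and two `moving` records never touch (a transit must
connect two located states). A located record following a located record
in a *different* region with no `moving` record between them is a **log
discontinuity**: the transit was never captured (sensor dropout). It is
surfaced as a warning and deliberately carries no place-vector mass —
counting it as a move would fabricate a transit the sensors never saw.
This convention also makes the canonical single-window example (three
changes in one region, two in a second, a move into a third) expressible
as a well-formed log.

## Place vectors

Each tumbling window of length `w` (default 20 s — one sub-interval of
the default graph configuration, so occupancy is resolved at sub-interval
granularity) yields a vector with one component per region. A
within-region change (repeated located record, or a resolved move whose
origin equals its destination) contributes 1 to its region; a
between-region move contributes 0.5 to origin and destination, attributed
to the window containing the `moving` record's timestamp. Windows are
half-open `[t, t+w)`, so total mass over all windows equals the number of
position-change events. The alternative `space="nodes"` widens vectors to
one component per sensor node (a region's mass on its first node) for
compatibility with node-indexed vector layouts; semantics stay
region-level.

## Ward clustering

Both clustering phases use an in-package agglomerative Ward
implementation: squared merge costs maintained by the Lance–Williams
recurrence, merge heights reported as `sqrt(2|a||b|/(|a|+|b|)) · ||c_a −
c_b||` (the convention scipy's `linkage` uses, which the test suite
cross-checks bit-for-bit on tie-free data). Merging halts when the
requested number of clusters remains. Determinism: points are ordered by
timestamp; original points get ids `0..m−1` and the cluster created by
merge `t` gets id `m+t`; exact distance ties resolve to the
lexicographically smallest id pair. With duplicate-heavy inputs (many
all-zero vectors from quiet periods) distance-0 merges can exhaust the
merge budget before all duplicates coalesce, leaving several clusters
with identical centroids; this is the faithful consequence of halting at
a preset `K` and is harmless downstream because assignment is
nearest-centroid with lowest-label tie-breaking.

Complexity is O(m²) memory and roughly O(m²) time per merge in the worst
case; series up to a few thousand vectors cluster in seconds.

## Representative series and transition graphs

The label series (nearest-centroid label per vector window) is integrated
over each sub-interval; the label with the largest occupancy duration is
the representative (ties to the lowest label). An empty sub-interval —
possible only with gapped logs — inherits the previous representative.
The trailing partial interval is dropped. Per interval, the `n`
consecutive representative steps define the directed multigraph counted
in a fixed `K1×K1` adjacency matrix; the final step wraps to the next
interval's first representative, and the last interval of a session
closes on a self-loop of its own last representative so every matrix sums
to exactly `n`. Embedding all graphs in the full phase-1 label universe
keeps the matrices mutually comparable for phase 2; phase-2 distance is
Euclidean on row-major flattened matrices (Frobenius).

**Quantizer consistency.** The pipeline builds the representative series
through nearest-centroid assignment for the training data too, not the
fitted Ward partition. With duplicate centroids (see above), fitted
labels and nearest-centroid labels can disagree on identical vectors;
scoring training and later streaming/anomaly data through different
quantizers would make training graphs artificially diverse. The
`labels=` override on `representative_series` still accepts an explicit
label sequence.

## Situation mapping

Each phase-2 cluster is summarised by its self-loop composition (fraction
of total edge weight on each phase-1 label's self-loop), off-diagonal
fraction, hour-of-day histogram of its intervals, centroid matrix and
graph count. An ordered YAML rule list maps summaries to scenario names;
all stated conditions of a rule must hold and the first match wins. The
shipped defaults name transition-heavy clusters (`offdiag ≥ 0.3`)
`movement-onset` and self-loop-dominated clusters `night-rest` /
`day-rest` / `quiet-rest` by their hour-of-day concentration, with night
defined as 20:00–08:00 (configurable). Timestamps are session-relative,
so hour bins assume a midnight session start unless the caller shifts
them.

## Movement metrics and anomaly flagging

`moving_fraction` reports, per tumbling window (default 1 h), 100× the
moving-state time overlapping the window divided by the window length;
record spans are clipped to window boundaries, making the metric
invariant to splitting a transit into contiguous parts. The attention
flag is strict: a window at exactly the 30% threshold is not flagged.

`detect_anomaly` scores a graph by Frobenius distance to the nearest
phase-2 centroid and compares against `mean + k·sd` (default `k = 3`) of
that cluster's training-member distances, cached at fit time; a
degenerate cluster with zero spread falls back to an absolute tolerance
(1e-9), so only exact replicas of a singleton pattern pass. The verdict
is monotone in distance by construction.

## Synthetic-data generator

The simulator is a semi-Markov renewal model per scheduled regime: dwell
times between position changes are exponential with the regime's mean;
each change is a between-region move with probability `move_prob`
(exponential transit duration, destination drawn from `region_weights`)
and a within-region reposition otherwise. Regime schedules express
day/night structure and low/high-movement phases; `inject_anomaly`
splices a window simulated from a different regime into an existing log,
clipping and re-deriving dwell times so all log invariants hold. One
seeded generator drives each log, so a fixed seed reproduces a log
byte-for-byte.

What the generator emulates: piecewise-stationary region occupancy,
occasional between-region transits with recorded durations, regime
changes on a wall clock, injectable agitation bursts. What it does not:
raw per-sensor waveforms (heart rate, breathing), posture/orientation,
measurement noise in region detection, multi-day circadian drift, or
staff-interaction events. Tests passing on simulated data therefore
validate the pipeline's mechanics and its behaviour under the stated
statistical structure, not clinical performance on real wards.

### Designed study conditions

Two end-to-end properties are checked on designed scenarios, sized so the
full suite runs comfortably on one CPU (3 h sessions, 20 seeds each):

* **Regime recovery.** Three regimes with disjoint region preferences
  cycled in 30-minute blocks; phase-2 assignments are compared with the
  block schedule by adjusted Rand index (median over seeds ≥ 0.8).
  Because place vectors count position *changes*, regimes are
  distinguishable only through where changes happen — a patient lying
  still produces the zero vector regardless of region. The scenario
  therefore uses restless regimes (mean dwell 12 s, `move_prob` 0.2) in
  disjoint bed areas; regimes differing only in resting location are a
  known blind spot of change-count features.
* **Anomaly detection.** Baseline night-rest (dwell 240 s, `move_prob`
  0.05, head-end regions) with a 30-minute agitation burst (dwell 10 s,
  `move_prob` 0.4) injected into an independently simulated night.
  Agitation is confined to the baseline's own regions: nearest-centroid
  quantization maps spread-thin or novel-region vectors onto the zero
  centroid (every trained centroid has zero mass there), which would hide
  the burst; in-region agitation instead drives label churn among known
  clusters, which the graph distance sees. Interval graphs overlapping
  the burst count as positives; pooled sensitivity ≥ 0.8 and
  false-positive rate ≤ 0.1 at `k = 3`.

## Defaults

| Parameter | Default | Meaning |
| --- | --- | --- |
| `k1` | 8 | phase-1 (place-vector) cluster count |
| `k2` | 5 | phase-2 (graph) cluster count |
| `interval_length_s` | 200 | outer interval for graph construction |
| `n_sub` | 10 | sub-intervals per interval (graph weight sum) |
| `vector_window_s` | 20 | place-vector tumbling window |
| `metrics_window_s` | 3600 | moving-fraction window |
| `attention_threshold_pct` | 30 | strict flagging threshold |
| `anomaly_k_sigma` | 3 | anomaly distance threshold multiplier |

Cluster counts are plain configuration: the method offers no internal
criterion for choosing them, so they are set from prior knowledge of the
ward routine being modelled.

## Known limitations

* Spatial information is heavily quantized before the temporal phase;
  anomalies expressible only in directions absent from training centroids
  are invisible to the graph distance (see above).
* Phase-1 labels depend on pooled fitting; per-session fitting would give
  incomparable label universes across sessions.
* The sensor-grouping scan (`dedupe=False`) reproduces the literal
  overlapping-group semantics of a seed-per-sensor neighbourhood scan;
  the default connected-components mode is the usable variant.
* Node-count configuration is honoured but the shipped layout fixes 10
  nodes / 5 regions; logs referencing other layouts must supply their own
  layout file.
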