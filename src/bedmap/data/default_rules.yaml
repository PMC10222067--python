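# Default cluster-to-situation rules. First matching rule wins.
# night_hours lists the hour-of-day bins counted as night (20:00-08:00).
night_hours: [20, 21, 22, 23, 0, 1, 2, 3, 4, 5, 6, 7]
rules:
  # Transition-heavy clusters: the patient keeps switching spatial patterns,
  # typical around the start of movement episodes.
  - scenario: movement-onset
    offdiag_min: 0.3
  # Stable occupancy clusters concentrated in night hours.
  - scenario: night-rest
    offdiag_max: 0.3
    dominant_selfloop_min: 0.5
    night_fraction_min: 0.7
  # Stable occupancy clusters concentrated in day hours.
  - scenario: day-rest
    offdiag_max: 0.3
    dominant_selfloop_min: 0.5
    day_fraction_min: 0.7
  # Any other stable-occupancy cluster.
  - scenario: quiet-rest
    offdiag_max: 0.3
    dominant_selfloop_min: 0.5
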