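import warnings

import numpy as np
import pytest

from bedmap import (
    BedLayout,
    BehaviorLog,
    BehaviorRecord,
    RegimeSpec,
    SimulationConfig,
    default_layout,
    simulate_log,
)


@pytest.fixture(scope="session")
def layout() -> BedLayout:
    return default_layout()


@pytest.fixture(scope="session")
def calm_regime() -> RegimeSpec:
    """Night-rest-like regime: occasional repositioning near the head end."""
    return RegimeSpec(
        "calm", (0.6, 0.4, 0.0, 0.0, 0.0),
        mean_dwell_s=240.0, move_prob=0.05, mean_move_duration_s=5.0,
    )


@pytest.fixture(scope="session")
def agitated_regime() -> RegimeSpec:
    """High-movement regime: rapid repositioning across the whole bed."""
    return RegimeSpec(
        "agitated", (0.2, 0.2, 0.2, 0.2, 0.2),
        mean_dwell_s=15.0, move_prob=0.7, mean_move_duration_s=8.0,
    )


@pytest.fixture
def make_log(layout):
    """Factory for single-regime simulated logs."""

    def _make(seed=0, duration=3600.0, regime=None):
        regime = regime or RegimeSpec(
            "mixed", (0.3, 0.3, 0.2, 0.1, 0.1),
            mean_dwell_s=60.0, move_prob=0.3, mean_move_duration_s=5.0,
        )
        cfg = SimulationConfig(
            ((0.0, duration, regime),), duration, seed=seed, layout=layout
        )
        return simulate_log(cfg)

    return _make


@pytest.fixture
def worked_example_log(layout) -> BehaviorLog:
    """The canonical single-window scenario: three position changes in one
    region, two in a second, and one move from the second into a third.

    The r1->r3 jump has no MOVING record, making it a log discontinuity
    that carries no place-vector mass."""
    records = [
        BehaviorRecord("r1", 0.0),
        BehaviorRecord("r1", 10.0),
        BehaviorRecord("r1", 20.0),
        BehaviorRecord("r1", 30.0),
        BehaviorRecord("r3", 40.0),
        BehaviorRecord("r3", 50.0),
        BehaviorRecord("r3", 60.0),
        BehaviorRecord("moving", 70.0, 5.0),
        BehaviorRecord("r4", 75.0, 25.0),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return BehaviorLog(records, layout).with_recomputed_dwell()
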