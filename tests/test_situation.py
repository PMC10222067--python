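import numpy as np
import pytest

from bedmap import (
    BehaviorLog,
    BehaviorRecord,
    SituationRule,
    TransitionGraph,
    attention_flags,
    default_rules,
    detect_anomaly,
    fit_phase2,
    map_to_situations,
    moving_fraction,
    summarize_clusters,
)
from bedmap.logmodel import MOVING
from bedmap.situation import NIGHT_HOURS, _rules_from_doc
from oracles import moving_overlap


def loop_graph(idx, label, K=3, n=10, start=0.0):
    A = np.zeros((K, K), dtype=int)
    A[label - 1, label - 1] = n
    return TransitionGraph(idx, A, start)


def mixed_graph(idx, K=3, start=0.0):
    A = np.zeros((K, K), dtype=int)
    A[0, 1] = 5
    A[1, 0] = 5
    return TransitionGraph(idx, A, start)


class TestSummaries:
    def test_pure_self_loop_cluster_composition(self):
        graphs = [loop_graph(i, 1) for i in range(4)]
        model = fit_phase2(graphs, 1)
        (s,) = summarize_clusters(model, graphs)
        assert s.selfloop_composition[1] == pytest.approx(1.0)
        assert s.offdiag_fraction == pytest.approx(0.0)
        assert s.dominant_selfloop == (1, pytest.approx(1.0))

    def test_night_graphs_fill_only_night_bins(self):
        starts = [21 * 3600.0, 23 * 3600.0, 2 * 3600.0, 5 * 3600.0]
        graphs = [loop_graph(i, 1, start=t) for i, t in enumerate(starts)]
        model = fit_phase2(graphs, 1)
        (s,) = summarize_clusters(model, graphs)
        assert s.temporal_histogram.sum() == 4
        assert s.hour_fraction(sorted(NIGHT_HOURS)) == pytest.approx(1.0)

    def test_summaries_match_brute_force_recomputation(self):
        rng = np.random.default_rng(0)
        graphs = [
            TransitionGraph(i, rng.integers(0, 3, size=(4, 4)), float(i) * 900.0)
            for i in range(20)
        ]
        model = fit_phase2(graphs, 3)
        summaries = summarize_clusters(model, graphs)
        for s in summaries:
            member = [
                g for g, a in zip(graphs, model.assignments) if a == s.cluster_label
            ]
            total = sum(g.adjacency.sum() for g in member)
            for j in range(4):
                expected = sum(g.adjacency[j, j] for g in member) / total
                assert abs(s.selfloop_composition[j + 1] - expected) < 1e-12
            off = sum(
                g.adjacency.sum() - np.trace(g.adjacency) for g in member
            ) / total
            assert abs(s.offdiag_fraction - off) < 1e-12
            assert s.graph_count == len(member)

    def test_composition_sums_to_one(self):
        graphs = [mixed_graph(i) for i in range(3)] + [loop_graph(3 + i, 2) for i in range(3)]
        model = fit_phase2(graphs, 2)
        for s in summarize_clusters(model, graphs):
            total = sum(s.selfloop_composition.values()) + s.offdiag_fraction
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_rejected(self):
        graphs = [loop_graph(i, 1) for i in range(3)]
        model = fit_phase2(graphs, 1)
        with pytest.raises(ValueError, match="length"):
            summarize_clusters(model, graphs, timestamps=[0.0])


class TestSituationRules:
    def test_empty_rule_list_leaves_all_unmapped(self):
        graphs = [loop_graph(i, 1) for i in range(3)]
        model = fit_phase2(graphs, 1)
        sit = map_to_situations(summarize_clusters(model, graphs), [])
        assert sit.entries == {1: "unmapped"}

    def test_offdiag_rule_catches_transition_heavy_cluster(self):
        graphs = [mixed_graph(i) for i in range(3)] + [
            loop_graph(3 + i, 2) for i in range(3)
        ]
        model = fit_phase2(graphs, 2)
        rules = [SituationRule(scenario="movement-onset", offdiag_min=0.5)]
        sit = map_to_situations(summarize_clusters(model, graphs), rules)
        values = set(sit.entries.values())
        assert values == {"movement-onset", "unmapped"}
        # the transition-heavy cluster is the one holding the mixed graphs
        mixed_label = model.assignments[0]
        assert sit.entries[mixed_label] == "movement-onset"

    def test_first_matching_rule_wins(self):
        graphs = [loop_graph(i, 1) for i in range(3)]
        model = fit_phase2(graphs, 1)
        rules = [
            SituationRule(scenario="first", dominant_selfloop_min=0.5),
            SituationRule(scenario="second", dominant_selfloop_min=0.5),
        ]
        sit = map_to_situations(summarize_clusters(model, graphs), rules)
        assert sit.entries[1] == "first"

    def test_malformed_rule_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            _rules_from_doc({"rules": [{"offdiag_min": 0.5}]})  # no scenario

    def test_default_rules_on_day_night_simulation(self, layout, calm_regime, agitated_regime):
        """On a simulated day/night log the shipped rules send self-loop
        dominated night clusters to rest scenarios and transition-heavy
        clusters to movement onset."""
        from bedmap import (
            SimulationConfig,
            extract_place_vectors,
            fit_phase1,
            representative_series,
            build_graphs,
            simulate_log,
        )

        day = 86400.0
        cfg = SimulationConfig(
            (
                (0.0, 8 * 3600.0, calm_regime),          # 00:00-08:00 night
                (8 * 3600.0, 20 * 3600.0, agitated_regime),  # day activity
                (20 * 3600.0, day, calm_regime),         # night again
            ),
            day,
            seed=21,
            layout=layout,
        )
        log = simulate_log(cfg)
        # coarser windows keep the duplicate-heavy Ward instance small
        series = extract_place_vectors(log, 60.0)
        m1 = fit_phase1(series, 8)
        rep = representative_series(m1, series, 1200.0, 10, labels=m1.assignments)
        graphs = build_graphs(rep, 8)
        m2 = fit_phase2(graphs, 5)
        summaries = summarize_clusters(m2, graphs)
        sit = map_to_situations(summaries, default_rules())
        assert set(sit.entries) == {1, 2, 3, 4, 5}
        for s in summaries:
            name = sit.entries[s.cluster_label]
            if s.offdiag_fraction >= 0.3:
                assert name == "movement-onset"
            elif s.dominant_selfloop[1] >= 0.5 and s.hour_fraction(sorted(NIGHT_HOURS)) >= 0.7:
                assert name == "night-rest"
        assert "movement-onset" in sit.entries.values()
        assert "night-rest" in sit.entries.values()


class TestMovingFraction:
    def test_all_moving_log_is_100pct(self, layout):
        log = BehaviorLog([BehaviorRecord(MOVING, 0.0, 500.0)], layout)
        metrics = moving_fraction(log, 100.0)
        np.testing.assert_allclose(metrics.moving_fraction_pct, 100.0)

    def test_no_moving_log_is_0pct(self, layout):
        log = BehaviorLog([BehaviorRecord("r1", 0.0, 500.0)], layout)
        metrics = moving_fraction(log, 100.0)
        np.testing.assert_allclose(metrics.moving_fraction_pct, 0.0)

    @pytest.mark.parametrize("seed,window", [(0, 60.0), (1, 3600.0), (2, 137.0)])
    def test_matches_overlap_integrator(self, make_log, seed, window):
        log = make_log(seed=seed, duration=7200.0)
        metrics = moving_fraction(log, window)
        for start, pct in zip(metrics.window_starts, metrics.moving_fraction_pct):
            expected = 100.0 * moving_overlap(log, start, start + window) / window
            assert abs(pct - expected) < 1e-9

    def test_invariant_to_splitting_a_moving_record(self, layout):
        whole = BehaviorLog(
            [
                BehaviorRecord("r1", 0.0, 50.0),
                BehaviorRecord(MOVING, 50.0, 40.0),
                BehaviorRecord("r2", 90.0, 110.0),
            ],
            layout,
        )
        split = BehaviorLog(
            [
                BehaviorRecord("r1", 0.0, 50.0),
                BehaviorRecord(MOVING, 50.0, 20.0),
                BehaviorRecord("r1", 70.0, 0.0),
                BehaviorRecord(MOVING, 70.0, 20.0),
                BehaviorRecord("r2", 90.0, 110.0),
            ],
            layout,
        )
        a = moving_fraction(whole, 25.0)
        b = moving_fraction(split, 25.0)
        np.testing.assert_allclose(a.moving_fraction_pct, b.moving_fraction_pct)

    def test_summary_stats_consistent(self, make_log):
        metrics = moving_fraction(make_log(seed=3), 600.0)
        assert metrics.min_pct <= metrics.mean_pct <= metrics.max_pct
        assert 0.0 <= metrics.min_pct and metrics.max_pct <= 100.0


class TestAttentionFlags:
    def test_zero_metrics_never_flag(self, layout):
        log = BehaviorLog([BehaviorRecord("r1", 0.0, 500.0)], layout)
        assert not attention_flags(moving_fraction(log, 100.0)).any()

    def test_exactly_30pct_not_flagged(self, layout):
        log = BehaviorLog(
            [
                BehaviorRecord("r1", 0.0, 70.0),
                BehaviorRecord(MOVING, 70.0, 30.0),
                BehaviorRecord("r2", 100.0, 0.0),
            ],
            layout,
        )
        metrics = moving_fraction(log, 100.0)
        assert metrics.moving_fraction_pct[0] == pytest.approx(30.0)
        assert not attention_flags(metrics, 30.0).any()
        assert attention_flags(metrics, 29.9).any()

    def test_injected_anomaly_window_flagged(self, layout, calm_regime, agitated_regime):
        from bedmap import SimulationConfig, inject_anomaly, simulate_log

        cfg = SimulationConfig(((0.0, 21600.0, calm_regime),), 21600.0, 30, layout)
        log = inject_anomaly(simulate_log(cfg), (7200.0, 9000.0), agitated_regime, seed=31)
        metrics = moving_fraction(log, 1800.0)
        flags = attention_flags(metrics, 30.0)
        idx = [int(s // 1800.0) for s in metrics.window_starts]
        flagged = {i for i, f in zip(idx, flags) if f}
        assert 4 in flagged  # the injected 7200-9000 s window
        assert not flags[:3].any()  # calm early-night windows stay quiet


class TestDetectAnomaly:
    @pytest.fixture
    def model(self):
        rng = np.random.default_rng(5)
        graphs = []
        for i in range(12):
            A = np.zeros((3, 3), dtype=int)
            A[0, 0] = 10 - (i % 3)
            A[0, 1] = i % 3
            graphs.append(TransitionGraph(i, A))
        return fit_phase2(graphs, 2)

    def test_centroid_graph_not_anomalous(self):
        graphs = [loop_graph(i, 1) for i in range(4)] + [
            loop_graph(4 + i, 2) for i in range(4)
        ]
        exact = fit_phase2(graphs, 2)
        is_anom, dist, label = detect_anomaly(loop_graph(0, 1), exact)
        assert not is_anom
        assert dist == pytest.approx(0.0, abs=1e-12)

    def test_never_seen_edge_pattern_is_anomalous(self, model):
        A = np.zeros((3, 3), dtype=int)
        A[2, 1] = 10
        is_anom, dist, _ = detect_anomaly(TransitionGraph(0, A), model)
        assert is_anom and dist > 1.0

    def test_shape_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="shape"):
            detect_anomaly(TransitionGraph(0, np.zeros((4, 4), dtype=int)), model)

    def test_monotone_in_distance(self, model):
        """Scaling a deviation away from a centroid never turns an
        anomalous verdict back to normal."""
        base = model.centroid_matrices[0]
        direction = np.zeros((3, 3))
        direction[2, 2] = 1.0
        prev_anom = False
        for scale in (0.5, 2.0, 5.0, 20.0):
            A = base + scale * direction
            g = TransitionGraph(0, A)
            is_anom, dist, _ = detect_anomaly(g, model)
            if prev_anom:
                assert is_anom
            prev_anom = is_anom

    def test_training_graphs_rarely_flagged(self, make_log):
        from bedmap import (
            build_graphs,
            extract_place_vectors,
            fit_phase1,
            representative_series,
        )

        series = extract_place_vectors(make_log(seed=6, duration=21600.0), 20.0)
        m1 = fit_phase1(series, 8)
        rep = representative_series(m1, series, 200.0, 10, labels=m1.assignments)
        graphs = build_graphs(rep, 8)
        m2 = fit_phase2(graphs, 5)
        flagged = sum(detect_anomaly(g, m2, 3.0)[0] for g in graphs)
        assert flagged / len(graphs) <= 0.05
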