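"""Connectome metrics: matching, PR variants, baseline, orphan filtering."""

import numpy as np
import pytest

from polysyn.core_io import (
    ConnectomeGraph,
    LabelVolume,
    PartnerEntry,
    PointAnnotation,
    SynapseRecord,
    Volume,
)
from polysyn.errors import ConfigError
from polysyn import connectome_eval as ce


def _pt(z, y, x, conf=1.0):
    return PointAnnotation(z, y, x, conf, "tbar")


def _rec(tbar, partners, host=None):
    return SynapseRecord(tbar, tuple(PartnerEntry(b, c) for b, c in partners), host)


def random_graph_pair(rng, n_nodes=12, max_weight=15):
    """A random (ground-truth, predicted) graph pair sharing some edges."""
    nodes = range(1, n_nodes + 1)
    g, p = ConnectomeGraph(), ConnectomeGraph()
    for a in nodes:
        for b in nodes:
            if a == b:
                continue
            if rng.random() < 0.15:
                g.add_edge(a, b, int(rng.integers(1, max_weight + 1)))
            if rng.random() < 0.15:
                p.add_edge(a, b, int(rng.integers(1, max_weight + 1)))
    return g, p


class TestMatchTbars:
    def test_identical_sets_perfect_matching(self):
        pts = [_pt(5, 5, 5), _pt(20, 20, 20)]
        m = ce.match_tbars(pts, pts, ce.MatchConfig(max_distance=5))
        assert len(m.pairs) == 2 and all(d == 0 for _, _, d in m.pairs)

    def test_one_to_one_near_single_gt(self):
        pred = [_pt(5, 5, 5), _pt(5, 5, 7)]
        gt = [_pt(5, 5, 6)]
        m = ce.match_tbars(pred, gt, ce.MatchConfig(max_distance=5))
        assert len(m.pairs) == 1

    def test_segment_constraint_toggles_match(self):
        data = np.ones((12, 12, 12), dtype=np.int64)
        data[:, :, 6:] = 2
        labels = LabelVolume(data)
        pred, gt = [_pt(5, 5, 7)], [_pt(5, 5, 4)]  # 3 voxels apart, across boundary
        loose = ce.match_tbars(pred, gt, ce.MatchConfig(max_distance=5))
        strict = ce.match_tbars(
            pred, gt, ce.MatchConfig(max_distance=5, require_same_segment=True), labels
        )
        assert len(loose.pairs) == 1 and len(strict.pairs) == 0

    def test_missing_labels_or_volume_rejected(self):
        with pytest.raises(ConfigError):
            ce.match_tbars([], [], ce.MatchConfig(require_same_segment=True))
        with pytest.raises(ConfigError):
            ce.match_tbars([], [], ce.MatchConfig(apply_shift=True))

    def test_greedy_prefers_nearest_pair(self):
        pred = [_pt(0, 0, 4)]
        gt = [_pt(0, 0, 0), _pt(0, 0, 5)]
        m = ce.match_tbars(pred, gt, ce.MatchConfig(max_distance=10))
        assert m.pairs == [(0, 1, 1.0)]

    def test_optimal_matches_at_least_as_many_as_greedy(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            pred = [_pt(*map(int, rng.integers(0, 30, 3))) for _ in range(6)]
            gt = [_pt(*map(int, rng.integers(0, 30, 3))) for _ in range(6)]
            cfg = ce.MatchConfig(max_distance=12)
            greedy = ce.match_tbars(pred, gt, cfg)
            optimal = ce.match_tbars(pred, gt, cfg, optimal=True)
            assert len(optimal.pairs) >= len(greedy.pairs)


class TestSynapseLevelPR:
    def test_perfect_prediction(self):
        gt = [_rec(_pt(5, 5, 5), [(2, 1.0), (3, 1.0)])]
        curve = ce.synapse_level_pr(gt, gt)
        assert all(p.precision == 1.0 and p.recall == 1.0 for p in curve)

    def test_hand_counted_partial_overlap(self):
        gt = [_rec(_pt(5, 5, 5), [(2, 1.0), (3, 1.0)])]
        pred = [_rec(_pt(5, 5, 6), [(2, 0.9), (4, 0.9)])]
        curve = ce.synapse_level_pr(pred, gt, thresholds=[0.5])
        [point] = curve
        assert (point.tp, point.fp, point.fn) == (1, 1, 1)
        assert point.precision == 0.5 and point.recall == 0.5

    def test_no_predictions_conventions(self):
        gt = [_rec(_pt(5, 5, 5), [(2, 1.0)])]
        [point] = ce.synapse_level_pr([], gt, thresholds=[0.5])
        assert point.precision == 1.0 and point.recall == 0.0

    def test_recall_non_increasing_in_threshold(self):
        rng = np.random.default_rng(11)
        gt = [_rec(_pt(10 * i + 5, 5, 5), [(2, 1.0)]) for i in range(4)]
        pred = [
            _rec(_pt(10 * i + 5, 5, 6), [(int(rng.integers(2, 5)), float(rng.random()))])
            for i in range(4)
        ]
        curve = ce.synapse_level_pr(pred, gt)
        recalls = [p.recall for p in curve]
        assert recalls == sorted(recalls, reverse=True)


class TestGraphWeightedPR:
    def test_seven_of_nine_equals_missing_strength_two(self):
        g = ConnectomeGraph({(1, 2): 9})
        p = ConnectomeGraph({(1, 2): 7})
        precision, recall = ce.graph_weighted_pr(g, p)
        assert precision == 1.0
        assert recall == pytest.approx(7 / 9)
        assert (1 - recall) * g.total_weight() == pytest.approx(2.0)

    def test_identity(self):
        g = ConnectomeGraph({(1, 2): 3, (4, 5): 1})
        assert ce.graph_weighted_pr(g, g) == (1.0, 1.0)

    def test_matches_per_unit_synapse_matching(self):
        # independent oracle: one unit per synapse, matched within each edge
        rng = np.random.default_rng(21)
        for _ in range(50):
            g, p = random_graph_pair(rng, n_nodes=6, max_weight=8)
            matched = sum(
                min(g.weight(e), p.weight(e)) for e in g.edge_set() | p.edge_set()
            )
            precision, recall = ce.graph_weighted_pr(g, p)
            assert precision == (matched / p.total_weight() if p.total_weight() else 1.0)
            assert recall == (matched / g.total_weight() if g.total_weight() else 1.0)


class TestGraphUnweightedPR:
    def test_identity_at_t1(self):
        g = ConnectomeGraph({(1, 2): 1, (2, 3): 4, (3, 1): 2})
        assert ce.graph_unweighted_pr(g, g, 1) == (1.0, 1.0)

    def test_single_edge_thresholds(self):
        g = ConnectomeGraph({(1, 2): 9})
        p = ConnectomeGraph({(1, 2): 7})
        assert ce.graph_unweighted_pr(g, p, 1) == (1.0, 1.0)
        assert ce.graph_unweighted_pr(g, p, 8) == (1.0, 0.0)

    def test_three_edge_worked_example(self):
        g = ConnectomeGraph({(1, 2): 12, (2, 3): 10, (3, 4): 3})
        p = ConnectomeGraph({(1, 2): 6, (3, 4): 11})
        assert ce.graph_unweighted_pr(g, p, 10) == (0.0, 0.0)

    def test_invalid_threshold(self):
        with pytest.raises(ConfigError):
            ce.graph_unweighted_pr(ConnectomeGraph(), ConnectomeGraph(), 0)


class TestAsymmetricPR:
    def test_worked_example(self):
        g = ConnectomeGraph({(1, 2): 12, (2, 3): 10, (3, 4): 3})
        p = ConnectomeGraph({(1, 2): 6, (3, 4): 11})
        precision, recall = ce.asymmetric_pr(g, p, ce.AsymThresholds(10, 5))
        assert recall == 0.5  # only edge (1,2) has p >= 5 among g >= 10
        assert precision == 0.0  # edge (3,4) predicted strong but g < 5

    def test_equal_thresholds_reduce_to_symmetric(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            g, p = random_graph_pair(rng)
            for t in (1, 3, 7):
                assert ce.asymmetric_pr(g, p, ce.AsymThresholds(t, t)) == \
                    ce.graph_unweighted_pr(g, p, t)

    def test_identity(self):
        g = ConnectomeGraph({(1, 2): 12, (2, 3): 10})
        assert ce.asymmetric_pr(g, g, ce.AsymThresholds(10, 5)) == (1.0, 1.0)

    def test_t1_below_t2_rejected(self):
        with pytest.raises(ConfigError):
            ce.AsymThresholds(3, 5)


class TestConnectionsAddedMissed:
    def test_worked_example(self):
        g = ConnectomeGraph({(1, 2): 12, (2, 3): 10, (3, 4): 3})
        p = ConnectomeGraph({(1, 2): 6, (3, 4): 11})
        am = ce.connections_added_missed(g, p, ce.AsymThresholds(10, 5))
        assert am.missed_edges == {(2, 3)}
        assert am.added_edges == {(3, 4)}
        assert am.normalized_missed == 0.5 and am.normalized_added == 0.5

    def test_identity_empty_sets(self):
        g = ConnectomeGraph({(1, 2): 12})
        am = ce.connections_added_missed(g, g, ce.AsymThresholds(10, 5))
        assert not am.missed_edges and not am.added_edges

    def test_normalized_missed_complements_recall(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            g, p = random_graph_pair(rng)
            thr = ce.AsymThresholds(int(rng.integers(2, 9)), int(rng.integers(1, 3)))
            _, recall = ce.asymmetric_pr(g, p, thr)
            am = ce.connections_added_missed(g, p, thr)
            if any(w >= thr.t1 for w in g.edges.values()):
                assert am.normalized_missed + recall == pytest.approx(1.0)


class TestUndirectedView:
    def test_sums_antiparallel_edges(self):
        g = ConnectomeGraph({(1, 2): 3, (2, 1): 2})
        assert ce.undirected_view(g).edges == {(1, 2): 5}

    def test_hand_computed_pattern(self):
        g = ConnectomeGraph({(1, 2): 1, (2, 1): 1, (1, 3): 2})
        assert ce.undirected_view(g).edges == {(1, 2): 2, (1, 3): 2}

    def test_empty(self):
        assert len(ce.undirected_view(ConnectomeGraph())) == 0


class TestFilterOrphans:
    def _scene(self):
        data = np.ones((12, 12, 12), dtype=np.int64)
        data[:, :, 4:8] = 2
        data[:, :, 8:] = 3  # body 3 hosts nothing -> orphan
        labels = LabelVolume(data)
        gt = [_rec(_pt(5, 5, 2), [(2, 1.0)], host=1)]
        return labels, gt

    def test_no_orphans_identity(self):
        labels, gt = self._scene()
        gt.append(_rec(_pt(5, 5, 9), [(2, 1.0)], host=3))  # body 3 now hosts a T-bar
        pred = [_rec(_pt(5, 5, 2), [(2, 0.9)], host=1)]
        filtered, orphans = ce.filter_orphans(pred, labels, gt)
        assert filtered == pred and orphans == set()

    def test_orphan_prediction_removed_recall_untouched(self):
        labels, gt = self._scene()
        pred = [
            _rec(_pt(5, 5, 2), [(2, 0.9)], host=1),
            _rec(_pt(5, 5, 9), [(2, 0.9)], host=3),  # presynaptic body is an orphan
        ]
        filtered, orphans = ce.filter_orphans(pred, labels, gt)
        assert orphans == {3}
        assert len(filtered) == 1
        before = ce.synapse_level_pr(pred, gt, thresholds=[0.5])[0]
        after = ce.synapse_level_pr(filtered, gt, thresholds=[0.5])[0]
        assert after.recall == before.recall
        assert after.precision > before.precision

    def test_gt_records_never_modified(self):
        labels, gt = self._scene()
        snapshot = list(gt)
        ce.filter_orphans([], labels, gt)
        assert gt == snapshot


class TestProximityBaseline:
    def _two_bodies(self):
        data = np.ones((10, 10, 10), dtype=np.int64)
        data[:, :, 5:] = 2
        return LabelVolume(data)

    def test_weight_conservation_two_bodies(self):
        g = ce.proximity_baseline(self._two_bodies(), 50, seed=0)
        assert g.total_weight() == 50
        assert g.edge_set() <= {(1, 2), (2, 1)}

    def test_seed_determinism(self):
        a = ce.proximity_baseline(self._two_bodies(), 100, seed=4)
        b = ce.proximity_baseline(self._two_bodies(), 100, seed=4)
        assert a == b

    def test_direction_is_fair_coin(self):
        n = 10000
        g = ce.proximity_baseline(self._two_bodies(), n, seed=9)
        w = g.weight((1, 2))
        # binomial(n, 1/2): allow 4 standard deviations
        assert abs(w - n / 2) < 4 * np.sqrt(n) / 2

    def test_no_boundary_rejected(self):
        labels = LabelVolume(np.ones((5, 5, 5), dtype=np.int64))
        with pytest.raises(ValueError, match="boundary"):
            ce.proximity_baseline(labels, 10, seed=0)


class TestSweepPRCurve:
    def _scene(self):
        labels = LabelVolume(np.ones((12, 12, 12), dtype=np.int64))
        labels.data[:, :, 6:] = 2
        gt = [_rec(_pt(5, 5, 4), [(2, 1.0)], host=1)]
        from polysyn.core_io import build_graph

        gt_graph = build_graph(gt, labels).graph
        pred = [_rec(_pt(5, 5, 4), [(2, 0.8)], host=1)]
        return gt_graph, pred, labels

    def test_single_threshold_equals_direct_call(self):
        gt_graph, pred, labels = self._scene()
        from polysyn.core_io import build_graph

        curve = ce.sweep_pr_curve(gt_graph, pred, labels, thresholds=[0.5], mode="weighted")
        direct = ce.graph_weighted_pr(gt_graph, build_graph(pred, labels).graph)
        assert (curve[0].precision, curve[0].recall) == direct

    def test_recall_non_increasing(self):
        rng = np.random.default_rng(17)
        labels = LabelVolume(rng.integers(1, 5, size=(10, 10, 10)).astype(np.int64))
        gt, pred = [], []
        for i in range(8):
            z, y, x = (int(v) for v in rng.integers(0, 10, 3))
            host = int(labels.data[z, y, x])
            others = [b for b in (1, 2, 3, 4) if b != host]
            gt.append(_rec(_pt(z, y, x), [(rng.choice(others), 1.0)]))
            pred.append(_rec(_pt(z, y, x), [(rng.choice(others), float(rng.random()))]))
        from polysyn.core_io import build_graph

        gt_graph = build_graph(gt, labels).graph
        curve = ce.sweep_pr_curve(gt_graph, pred, labels, mode="weighted")
        recalls = [p.recall for p in curve]
        assert recalls == sorted(recalls, reverse=True)

    def test_empty_records_zero_recall(self):
        gt_graph, _, labels = self._scene()
        curve = ce.sweep_pr_curve(gt_graph, [], labels, thresholds=[0.0], mode="unweighted")
        assert curve[0].recall == 0.0
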