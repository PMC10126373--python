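"""Network-restricted masks, overlap networks, hubs, fixed-model application."""

import numpy as np
import pytest

import motioncpm as mc
from motioncpm.exceptions import PartitionError


@pytest.fixture
def partition():
    return mc.NetworkPartition(np.array(["A"] * 4 + ["B"] * 3 + ["C"] * 3))


def full_masks(n_edges):
    return mc.FeatureMasks(np.ones(n_edges, bool), np.zeros(n_edges, bool),
                           0.01, 50)


class TestRestrictMask:
    def test_within_keeps_only_internal_edges(self, partition):
        n = partition.n_nodes
        masks = full_masks(n * (n - 1) // 2)
        res = mc.restrict_mask(masks, partition, "within", "A")
        iu, ju = mc.edge_index_pairs(n)
        labels = partition.labels
        for k in range(masks.n_edges):
            expect = labels[iu[k]] == "A" and labels[ju[k]] == "A"
            assert res.positive[k] == expect

    def test_between_excludes_within_edges(self, partition):
        n = partition.n_nodes
        masks = full_masks(n * (n - 1) // 2)
        res = mc.restrict_mask(masks, partition, "between", ("A", "B"))
        iu, ju = mc.edge_index_pairs(n)
        labels = partition.labels
        for k in range(masks.n_edges):
            pair = {labels[iu[k]], labels[ju[k]]}
            assert res.positive[k] == (pair == {"A", "B"})

    def test_cells_partition_the_full_mask(self, partition):
        n = partition.n_nodes
        masks = full_masks(n * (n - 1) // 2)
        union = np.zeros(masks.n_edges, bool)
        count = np.zeros(masks.n_edges, int)
        for net in partition.networks:
            cell = mc.restrict_mask(masks, partition, "within", net).positive
            union |= cell
            count += cell
        for pair in partition.network_pairs():
            cell = mc.restrict_mask(masks, partition, "between", pair).positive
            union |= cell
            count += cell
        assert union.all()
        assert np.all(count == 1)  # disjoint and exhaustive

    def test_unknown_network_rejected(self, partition):
        masks = full_masks(45)
        with pytest.raises(PartitionError):
            mc.restrict_mask(masks, partition, "within", "Z")


class TestNetworkwisePrediction:
    def test_localizes_planted_within_structure(self, cfg):
        n_nodes = 30
        labels = np.array(["A"] * 8 + ["B"] * 8 + ["C"] * 7 + ["D"] * 7)
        part = mc.NetworkPartition(labels)
        cell = mc.edge_cell_mask(n_nodes, part, "within", "A")
        picker = np.random.default_rng(17)
        planted = tuple(sorted(picker.choice(np.where(cell)[0], 20,
                                             replace=False).tolist()))
        spec = mc.SyntheticSpec(n_subjects=100, n_nodes=n_nodes, n_frames=150,
                                coupling_edges=planted, coupling_strength=0.5,
                                artifact_gain=0.0, seed=11)
        cohort = mc.simulate_cohort(spec)
        edges = mc.cohort_edge_matrix(cohort, cfg)
        pred = mc.networkwise_prediction(edges, cohort.scores_rms_dd, part,
                                         cfg)
        rs = {k: (v.pearson_r if v is not None else -np.inf)
              for k, v in pred.within.items()}
        assert max(rs, key=rs.get) == "A"
        assert rs["A"] > pred.critical_r_within

    def test_tiny_cells_flagged_not_computable(self, cfg, rng):
        part = mc.NetworkPartition(np.array(["A", "A", "A", "A", "B"]))
        edges = rng.normal(0, 1, (30, 10))
        scores = rng.normal(0, 1, 30)
        pred = mc.networkwise_prediction(edges, scores, part, cfg)
        # within-B has zero candidate edges (single node)
        assert pred.within["B"] is None


class TestOverlapNetwork:
    def _random_masks(self, rng, n_edges=45, n_sets=6):
        out = []
        for _ in range(n_sets):
            r = rng.random(n_edges)
            out.append(mc.FeatureMasks(r > 0.7, r < 0.25, 0.01, 50))
        return out

    def test_identical_sets_reproduce_common_mask(self, rng):
        masks = self._random_masks(rng, n_sets=1) * 4
        net = mc.overlap_network(masks, min_fraction=1.0, n_nodes=10)
        np.testing.assert_array_equal(
            np.where(masks[0].positive)[0], net.positive_edges)
        np.testing.assert_array_equal(
            np.where(masks[0].negative)[0], net.negative_edges)

    def test_pairwise_disjoint_sets_give_empty_network(self):
        sets = []
        for k in range(3):
            pos = np.zeros(45, bool)
            pos[k * 15:(k + 1) * 15] = True
            sets.append(mc.FeatureMasks(pos, np.zeros(45, bool), 0.01, 50))
        net = mc.overlap_network(sets, min_fraction=0.5, n_nodes=10)
        assert net.n_edges_total == 0

    def test_matches_literal_counting_reference(self, rng):
        masks = self._random_masks(rng)
        frac = 0.5
        net = mc.overlap_network(masks, min_fraction=frac, n_nodes=10)
        for e in range(45):
            pos_n = sum(m.positive[e] for m in masks)
            neg_n = sum(m.negative[e] for m in masks)
            in_pos = pos_n >= frac * len(masks) and not (
                neg_n >= frac * len(masks) and neg_n >= pos_n)
            in_neg = neg_n >= frac * len(masks) and not (
                pos_n >= frac * len(masks) and pos_n >= neg_n)
            assert (e in net.positive_edges) == in_pos
            assert (e in net.negative_edges) == in_neg

    def test_monotone_in_min_fraction(self, rng):
        masks = self._random_masks(rng, n_sets=8)
        previous = None
        for frac in (0.25, 0.5, 0.75, 1.0):
            net = mc.overlap_network(masks, min_fraction=frac, n_nodes=10)
            current = set(net.positive_edges) | set(net.negative_edges)
            if previous is not None:
                assert current <= previous
            previous = current

    def test_degrees_invariant_to_set_order(self, rng):
        masks = self._random_masks(rng)
        d1 = mc.overlap_network(masks, 0.5, n_nodes=10).degrees()
        d2 = mc.overlap_network(masks[::-1], 0.5, n_nodes=10).degrees()
        np.testing.assert_array_equal(d1, d2)


class TestDegreeTable:
    def test_star_network(self):
        # node 0 connected to nodes 1..5 → degree 5, leaves degree 1
        iu, ju = mc.edge_index_pairs(6)
        idx = [k for k in range(len(iu)) if iu[k] == 0]
        net = mc.OverlapNetwork(np.array(idx), np.array([], dtype=int),
                                n_nodes=6, min_fraction=0.5, n_mask_sets=2)
        table = mc.node_degree_table(net)
        assert table.iloc[0]["node"] == 0 and table.iloc[0]["degree"] == 5
        assert (table.iloc[1:]["degree"] == 1).all()

    def test_empty_network_empty_table(self):
        net = mc.OverlapNetwork(np.array([], dtype=int),
                                np.array([], dtype=int), n_nodes=6,
                                min_fraction=0.5, n_mask_sets=2)
        assert len(mc.node_degree_table(net)) == 0

    def test_degrees_match_adjacency_count(self, rng):
        n_nodes = 12
        n_edges = n_nodes * (n_nodes - 1) // 2
        pick = rng.choice(n_edges, 20, replace=False)
        net = mc.OverlapNetwork(np.sort(pick[:12]), np.sort(pick[12:]),
                                n_nodes=n_nodes, min_fraction=0.5,
                                n_mask_sets=2)
        adj = np.zeros((n_nodes, n_nodes), dtype=int)
        iu, ju = mc.edge_index_pairs(n_nodes)
        for k in np.concatenate([net.positive_edges, net.negative_edges]):
            adj[iu[k], ju[k]] = adj[ju[k], iu[k]] = 1
        np.testing.assert_array_equal(net.degrees(), adj.sum(axis=1))


class TestApplyFixedNetwork:
    def test_zero_slopes_flagged(self, rng):
        net = mc.OverlapNetwork(np.array([0, 1]), np.array([2]), n_nodes=5,
                                min_fraction=0.5, n_mask_sets=2)
        res = mc.apply_fixed_network(net, a=0.5, b=0.0, c=0.0,
                                     cohort_edges=rng.normal(0, 1, (10, 10)),
                                     observed_scores=rng.normal(0, 1, 10))
        assert not res.valid

    def test_in_sample_consistency_with_direct_fit(self, cfg, planted_edges,
                                                   planted_cohort):
        # exporting full-sample masks + coefficients and re-applying them
        # must reproduce the in-sample fit exactly
        scores = planted_cohort.scores_rms_dd
        masks = mc.select_features(planted_edges, scores, cfg.selection_p)
        S = mc.strengths_matrix(planted_edges, masks)
        model = mc.fit_model(S[:, 0], S[:, 1], scores, "bilinear", masks)
        net = mc.OverlapNetwork(np.where(masks.positive)[0],
                                np.where(masks.negative)[0],
                                n_nodes=planted_cohort.spec.n_nodes,
                                min_fraction=1.0, n_mask_sets=2)
        applied = mc.apply_fixed_network(net, model.a, model.b, model.c,
                                         planted_edges, scores)
        fitted = mc.accuracy(scores, mc.predict(model, S[:, 0], S[:, 1]))
        assert applied.pearson_r == pytest.approx(fitted.pearson_r, abs=1e-10)

    def test_generalizes_to_matched_cohort(self, cfg, planted_edges,
                                           planted_cohort):
        # same planted edges, new subjects: the exported network+model
        # should still predict motion well above chance
        scores = planted_cohort.scores_rms_dd
        masks = mc.select_features(planted_edges, scores, cfg.selection_p)
        S = mc.strengths_matrix(planted_edges, masks)
        model = mc.fit_model(S[:, 0], S[:, 1], scores, "bilinear", masks)
        net = mc.OverlapNetwork(np.where(masks.positive)[0],
                                np.where(masks.negative)[0],
                                n_nodes=planted_cohort.spec.n_nodes,
                                min_fraction=1.0, n_mask_sets=2)
        spec2 = mc.SyntheticSpec(**{**planted_cohort.spec.__dict__,
                                    "seed": 22})
        cohort2 = mc.simulate_cohort(spec2)
        edges2 = mc.cohort_edge_matrix(cohort2, cfg)
        res = mc.apply_fixed_network(net, model.a, model.b, model.c, edges2,
                                     cohort2.scores_rms_dd)
        assert res.valid and res.pearson_r > 0.5
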