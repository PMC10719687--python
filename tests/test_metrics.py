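"""Centrality measures against hand-enumerated and brute-force oracles;
scaling/ranking rules; bridge extraction."""

import numpy as np
import pandas as pd
import pytest

from bridgenet.metrics import (
    centrality_table,
    extract_bridges,
    ratio_measures,
    scale_and_rank,
    shortest_path_centralities,
    weighted_degree,
)
from bridgenet.mgm import Network
from bridgenet.variables import (
    CATEGORICAL,
    CONTINUOUS,
    SpecificationError,
    VariableSpec,
)

from _bruteforce import brute_force_centralities, random_weighted_network


def _net(names, edges, groups=None, kinds=None):
    groups = groups or {}
    kinds = kinds or {}
    specs = [VariableSpec(n, kinds.get(n, CONTINUOUS),
                          4 if kinds.get(n) == CATEGORICAL else 0,
                          groups.get(n, "panel"), k) for k, n in enumerate(names)]
    net = Network(nodes=specs)
    for a, b, w in edges:
        net.add_edge(a, b, w, "+")
    return net


class TestWeightedDegree:
    def test_isolated_node_zero(self):
        net = _net(["a", "b", "c"], [("a", "b", 0.5)])
        assert weighted_degree(net, "c") == 0.0

    def test_path_degrees(self):
        net = _net(["a", "b", "c"], [("a", "b", 0.5), ("b", "c", 0.5)])
        assert weighted_degree(net, "b") == 1.0
        assert weighted_degree(net, "a") == 0.5

    def test_star_center_sums_weights(self):
        edges = [("c", f"l{i}", w) for i, w in enumerate([0.1, 0.2, 0.3, 0.4])]
        net = _net(["c", "l0", "l1", "l2", "l3"], edges)
        assert weighted_degree(net, "c") == pytest.approx(1.0)

    def test_unknown_node_rejected(self):
        net = _net(["a", "b"], [("a", "b", 1.0)])
        with pytest.raises(SpecificationError):
            weighted_degree(net, "zz")


class TestShortestPathCentralities:
    def test_star_betweenness_is_leaf_pair_count(self):
        names = ["c"] + [f"l{i}" for i in range(5)]
        net = _net(names, [("c", l, 1.0) for l in names[1:]])
        betw, close = shortest_path_centralities(net)
        assert betw["c"] == pytest.approx(10.0)          # C(5,2)
        assert all(betw[l] == 0.0 for l in names[1:])
        assert close["c"] == pytest.approx(1.0)          # all at distance 1

    def test_weak_edge_rerouted_through_third_node(self):
        # weights 1,1,0.2 -> lengths 1,1,5: a-b via c costs 2 < 5
        net = _net(["a", "b", "c"],
                   [("a", "c", 1.0), ("c", "b", 1.0), ("a", "b", 0.2)])
        betw, _ = shortest_path_centralities(net)
        assert betw["c"] == pytest.approx(1.0)
        assert betw["a"] == betw["b"] == 0.0

    def test_two_node_network_zero_betweenness(self):
        net = _net(["a", "b"], [("a", "b", 0.7)])
        betw, _ = shortest_path_centralities(net)
        assert betw == {"a": 0.0, "b": 0.0}

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            net = random_weighted_network(rng)
            lengths = {frozenset(k): 1.0 / w for k, (w, _) in net.edges.items()}
            betw, close = shortest_path_centralities(net)
            bf_b, bf_c = brute_force_centralities(net.node_names(), lengths)
            for v in net.node_names():
                assert betw[v] == pytest.approx(bf_b[v], abs=1e-9)
                assert close[v] == pytest.approx(bf_c[v], abs=1e-9)

    def test_uniform_weight_rescaling(self):
        rng = np.random.default_rng(32)
        net = random_weighted_network(rng)
        scaled = _net(net.node_names(),
                      [(a, b, 3 * w) for (a, b), (w, _) in net.edges.items()])
        b1, c1 = shortest_path_centralities(net)
        b2, c2 = shortest_path_centralities(scaled)
        for v in net.node_names():
            assert b1[v] == pytest.approx(b2[v], abs=1e-9)
            assert c2[v] == pytest.approx(3 * c1[v], rel=1e-9)


class TestRatiosAndScaling:
    def test_ratio_examples_and_zero_degree_guard(self):
        bd, cd = ratio_measures({"a": 10.0, "b": 0.0, "c": 1.0},
                                {"a": 4.0, "b": 2.0, "c": 1.0},
                                {"a": 2.0, "b": 5.0, "c": 0.0})
        assert bd["a"] == 5.0 and cd["a"] == 2.0
        assert bd["b"] == 0.0                       # zero betweenness
        assert bd["c"] == 0.0 and cd["c"] == 0.0    # isolated node guard

    def test_min_max_scaling(self):
        raw = pd.DataFrame({"m": [0.0, 5.0, 10.0]}, index=["a", "b", "c"])
        out = scale_and_rank(raw)
        np.testing.assert_allclose(out["m_scaled"], [0.0, 0.5, 1.0])

    def test_dense_tie_ranking(self):
        raw = pd.DataFrame({"m": [10.0, 10.0, 3.0, 1.0]},
                           index=list("abcd"))
        out = scale_and_rank(raw)
        assert out["m_rank"].tolist() == [1, 1, 2, 3]

    def test_constant_measure_scales_to_half(self):
        raw = pd.DataFrame({"m": [2.0, 2.0, 2.0]}, index=list("abc"))
        out = scale_and_rank(raw)
        assert (out["m_scaled"] == 0.5).all()

    def test_hub_flagged_top3_on_weighted_degree(self):
        names = ["hub"] + [f"n{i}" for i in range(6)]
        edges = [("hub", n, 0.9) for n in names[1:]]
        edges += [("n1", "n2", 0.1), ("n3", "n4", 0.1)]
        table = centrality_table(_net(names, edges))
        assert bool(table.loc["hub", "top3"])
        assert table.loc["hub", "weighted_degree_rank"] == 1

    def test_scaled_values_in_unit_interval(self, small_results):
        table = small_results.centrality()
        for m in ("betweenness", "closeness", "weighted_degree",
                  "betweenness_degree_ratio", "closeness_degree_ratio"):
            assert table[m + "_scaled"].between(0, 1).all()
            ranks = table[m + "_rank"]
            assert set(ranks) == set(range(1, ranks.max() + 1))  # dense


class TestExtractBridges:
    def _toy(self, cross_edges, intra_edges=()):
        names = ["s1", "s2", "s3", "m1", "m2", "m3"]
        groups = {"s1": "somatic", "s2": "somatic", "s3": "mood_cognition"}
        kinds = {s: CATEGORICAL for s in ("s1", "s2", "s3")}
        return _net(names, list(cross_edges) + list(intra_edges), groups, kinds)

    def test_no_cross_edges_empty(self):
        net = self._toy([], [("s1", "s2", 0.5), ("m1", "m2", 0.5)])
        assert extract_bridges(net).edges == []

    def test_enumerated_counts(self):
        net = self._toy([("s1", "m1", 0.3), ("s1", "m2", 0.2), ("s2", "m1", 0.1)])
        report = extract_bridges(net)
        assert report.n_bridges == 3
        assert report.symptoms_touched == {"s1", "s2"}
        assert report.metabolites_touched == {"m1", "m2"}
        assert report.somatic_touched == {"s1", "s2"}
        assert report.mood_cognition_touched == set()

    def test_coverage_percentages(self):
        # 2 of 2 somatic -> 100%; 0 of 1 mood/cognition -> 0%
        net = self._toy([("s1", "m1", 0.3), ("s2", "m2", 0.2)])
        report = extract_bridges(net)
        assert report.coverage("somatic") == pytest.approx(100.0)
        assert report.coverage("mood_cognition") == pytest.approx(0.0)

    def test_invariant_to_relabeling_within_groups(self):
        net1 = self._toy([("s1", "m1", 0.3), ("s2", "m2", 0.2)])
        net2 = self._toy([("s2", "m2", 0.3), ("s1", "m1", 0.2)])
        r1, r2 = extract_bridges(net1), extract_bridges(net2)
        assert r1.n_bridges == r2.n_bridges
        assert len(r1.somatic_touched) == len(r2.somatic_touched)

    def test_symptom_metabolite_partition_in_fitted_network(self, small_results):
        report = extract_bridges(small_results.network)
        for sym, met, w, _ in report.edges:
            assert small_results.network.spec(sym).is_symptom
            assert small_results.network.spec(met).is_metabolite
            assert w > 0
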