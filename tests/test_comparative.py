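"""Tests of neighborhood extraction, expansion and conservation scoring."""

import networkx as nx
import numpy as np
import pytest

import xylemnet as xn
from xylemnet.comparative import (
    OrthologMap,
    compare_species,
    conservation_test,
    expand,
    neighborhood,
    neighborhood_membership,
    tf_subset,
)
from xylemnet.network import CoexpressionNetwork


def net_from(edges, nodes=(), threshold=5.0):
    """edges: (u, v, clr_score) triples."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, s in edges:
        g.add_edge(u, v, clr_score=float(s), pearson_r=0.9, sign="+", zero_r=False)
    return CoexpressionNetwork(g, threshold)


class TestNeighborhood:
    def test_seed_without_qualifying_edges_alone(self):
        net = net_from([("a", "b", 5.0)], nodes=["s"])
        sub = neighborhood(net, "s")
        assert set(sub.nodes) == {"s"} and sub.number_of_edges() == 0

    def test_inclusive_threshold(self):
        net = net_from(
            [("s", "a", 5.0), ("s", "b", 5.0), ("s", "c", 6.0), ("s", "d", 4.9)],
            threshold=4.0,
        )
        sub = neighborhood(net, "s", 5.0)
        assert set(sub.nodes) == {"s", "a", "b", "c"}

    def test_multi_seed_union_matches_per_seed_oracle(self, rng):
        g = nx.gnp_random_graph(30, 0.15, seed=7)
        edges = [(str(u), str(v), float(rng.uniform(3, 7))) for u, v in g.edges]
        net = net_from(edges, threshold=3.0)
        seeds = ["0", "5", "9"]
        union = set()
        for s in seeds:
            union |= set(neighborhood(net, s, 5.0).nodes)
        combined = set(neighborhood(net, seeds, 5.0).nodes)
        assert combined == union

    def test_threshold_below_build_threshold_rejected(self):
        net = net_from([("a", "b", 6.0)])
        with pytest.raises(ValueError, match="upward"):
            neighborhood(net, "a", 4.0)

    def test_absent_seeds_reported_but_missing_all_is_error(self):
        net = net_from([("a", "b", 6.0)])
        sub = neighborhood(net, ["a", "nope"])
        assert sub.graph["absent_seeds"] == ["nope"]
        with pytest.raises(ValueError, match="no seed present"):
            neighborhood(net, ["nope"])


class TestExpand:
    def test_clique_is_fixed_point(self):
        edges = [(u, v, 6.0) for u, v in [("a", "b"), ("a", "c"), ("b", "c")]]
        net = net_from(edges)
        assert expand(net, {"a", "b", "c"}) == {"a", "b", "c"}

    def test_path_graph_expands_one_node_per_call(self):
        edges = [(f"n{i}", f"n{i+1}", 6.0) for i in range(5)]
        net = net_from(edges)
        current = {"n0"}
        for step in range(1, 5):
            current = expand(net, current)
            assert current == {f"n{i}" for i in range(step + 1)}

    def test_expansion_is_monotone(self, rng):
        g = nx.gnp_random_graph(20, 0.2, seed=1)
        edges = [(str(u), str(v), float(rng.uniform(4, 7))) for u, v in g.edges]
        net = net_from(edges, threshold=4.0)
        current = {"0", "3"}
        out = expand(net, current)
        assert out >= current

    def test_neighborhood_then_expand_equals_bfs_depth_two(self, rng):
        g = nx.gnp_random_graph(25, 0.15, seed=3)
        edges = [(str(u), str(v), float(rng.uniform(3, 7))) for u, v in g.edges]
        net = net_from(edges, threshold=3.0)
        theta = 4.5
        seed = "0"
        if seed not in net.graph:
            pytest.skip("seed isolated in this draw")
        one = set(neighborhood(net, seed, theta).nodes)
        two = expand(net, one, theta)
        # BFS oracle to depth 2 over qualifying edges only
        keep = nx.Graph(
            (u, v) for u, v, d in net.graph.edges(data=True) if d["clr_score"] >= theta
        )
        keep.add_nodes_from(net.graph.nodes)
        reach = {seed}
        frontier = {seed}
        for _ in range(2):
            frontier = {v for u in frontier for v in keep.neighbors(u)} - reach
            reach |= frontier
        assert two == reach


class TestTfSubset:
    def test_mixed_set(self):
        assert tf_subset(["a", "b", "c"], {"b", "z"}) == ["b"]

    def test_no_tfs_empty(self):
        assert tf_subset(["a", "b"], set()) == []

    def test_all_tfs_identity_with_order(self):
        assert tf_subset(["c", "a"], {"a", "c"}) == ["c", "a"]


class TestConservationTest:
    def identical_pair(self):
        edges_a = [("s", "t1", 6.0), ("s", "t2", 6.0), ("t1", "t2", 6.0)]
        net_a = net_from(edges_a)
        edges_b = [(u.upper(), v.upper(), s) for u, v, s in edges_a]
        net_b = net_from(edges_b)
        orth = OrthologMap([("s", "S"), ("t1", "T1"), ("t2", "T2")])
        return net_a, net_b, orth

    def test_identical_networks_fully_conserved(self):
        net_a, net_b, orth = self.identical_pair()
        row = conservation_test(net_a, net_b, orth, "s")
        assert row.overlap_fraction == 1.0
        assert row.verdict == "conserved"

    def test_seed_without_ortholog_untestable(self):
        net_a, net_b, _ = self.identical_pair()
        orth = OrthologMap([("t1", "T1"), ("t2", "T2")])
        row = conservation_test(net_a, net_b, orth, "s")
        assert row.verdict == "untestable"

    def test_neighbors_without_orthologs_excluded_from_denominator(self):
        net_a, net_b, _ = self.identical_pair()
        orth = OrthologMap([("s", "S"), ("t1", "T1")])  # t2 unmapped
        row = conservation_test(net_a, net_b, orth, "s")
        assert row.mapped_neighbors == {"t1"}
        assert row.overlap_fraction == 1.0

    def test_direction_symmetric_verdict_under_identity_map(self):
        net_a, net_b, orth = self.identical_pair()
        fwd = conservation_test(net_a, net_b, orth, "s")
        rev = conservation_test(net_b, net_a, orth.reversed(), "S")
        assert fwd.verdict == rev.verdict
        assert fwd.overlap_fraction == rev.overlap_fraction

    def test_raising_threshold_b_weakly_reduces_overlap(self):
        edges_a = [("s", "t1", 6.0), ("s", "t2", 6.0)]
        edges_b = [("S", "T1", 6.0), ("S", "T2", 5.0)]
        net_a, net_b = net_from(edges_a), net_from(edges_b, threshold=5.0)
        orth = OrthologMap([("s", "S"), ("t1", "T1"), ("t2", "T2")])
        lo = conservation_test(net_a, net_b, orth, "s", threshold_b=5.0)
        hi = conservation_test(net_a, net_b, orth, "s", threshold_b=5.5)
        assert hi.overlap_fraction <= lo.overlap_fraction

    def test_seed_absent_from_network_a_errors(self):
        net_a, net_b, orth = self.identical_pair()
        with pytest.raises(ValueError, match="absent"):
            conservation_test(net_a, net_b, orth, "missing")

    def test_best_mode_uses_single_ortholog(self):
        edges_a = [("s", "t1", 6.0)]
        edges_b = [("S", "X2", 6.0)]
        net_a, net_b = net_from(edges_a), net_from(edges_b, nodes=["X1"])
        # t1 maps to X1 (not in neighborhood) and X2 (in neighborhood)
        orth = OrthologMap([("s", "S"), ("t1", "X1"), ("t1", "X2")])
        any_row = conservation_test(net_a, net_b, orth, "s", mode="any")
        best_row = conservation_test(net_a, net_b, orth, "s", mode="best")
        assert any_row.overlap == 1
        assert best_row.overlap == 0  # X1 is the first ortholog in sorted order


class TestNeighborhoodMembership:
    def test_probe_states(self):
        net = net_from([("s", "a", 6.0), ("b", "c", 6.0)])
        out = neighborhood_membership(net, "s", ["s", "a", "b", "ghost"])
        assert out == {
            "s": "present-self",
            "a": "present",
            "b": "absent",
            "ghost": "absent-from-network",
        }

    def test_matches_adjacency_oracle(self, rng):
        g = nx.gnp_random_graph(20, 0.2, seed=9)
        edges = [(str(u), str(v), float(rng.uniform(4, 7))) for u, v in g.edges]
        net = net_from(edges, threshold=4.0)
        seed = "0"
        out = neighborhood_membership(net, seed, [str(i) for i in range(20)], threshold=5.0)
        for probe, state in out.items():
            if probe == seed:
                continue
            expected = (
                net.graph.has_edge(seed, probe)
                and net.graph.edges[seed, probe]["clr_score"] >= 5.0
            )
            assert (state == "present") == expected

    def test_missing_seed_errors(self):
        net = net_from([("a", "b", 6.0)])
        with pytest.raises(ValueError, match="seed"):
            neighborhood_membership(net, "zz", ["a"])


class TestPlantedDivergenceRecovery:
    @staticmethod
    def build_nets(n_diverged, seed=7):
        cfg = xn.SimulationConfig(
            n_genes=500, peak_width=0.1, nb_dispersion=0.05, amplitude=1600.0, rng_seed=seed
        )
        ma, mb, truth = xn.simulate_species_pair(cfg, 5, 8, n_diverged)

        def net_of(m):
            sf = xn.compute_size_factors(m)
            v = xn.vst_transform(m, sf)
            ve = v.subset_genes(xn.filter_expressed(v))
            clr = xn.clr_transform(xn.mutual_information(ve))
            return xn.build_network(ve, clr, 3.5)

        return net_of(ma), net_of(mb), truth

    def test_single_planted_diverged_seed_flagged_exactly(self):
        net_a, net_b, truth = self.build_nets(1)
        report = compare_species(
            net_a, net_b, xn.OrthologMap(truth.orthologs), sorted(truth.seed_targets_a),
            threshold_a=3.5, threshold_b=3.5,
        )
        flagged = set(report.loc[report["verdict"] == "diverged", "seed_a"])
        assert flagged == truth.diverged_seeds
        assert (report["verdict"] != "untestable").all()

    def test_all_diverged_scenario(self):
        net_a, net_b, truth = self.build_nets(5)
        report = compare_species(
            net_a, net_b, xn.OrthologMap(truth.orthologs), sorted(truth.seed_targets_a),
            threshold_a=3.5, threshold_b=3.5,
        )
        assert (report["verdict"] == "diverged").all()
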