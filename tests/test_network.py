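"""Tests of MI estimation, CLR correction, threshold selection and the
thresholded signed network."""

import networkx as nx
import numpy as np
import pytest

from conftest import make_matrix
from xylemnet.network import (
    CLRMatrix,
    MIMatrix,
    build_network,
    clr_transform,
    largest_subnetwork,
    mutual_information,
    select_threshold_scale_free,
)


def mi_of_pair(x, y, bins, scheme="equal_frequency"):
    m = make_matrix(np.vstack([x, y]), kind="vst")
    return mutual_information(m, bins=bins, scheme=scheme).values[0, 1]


def brute_force_clr(mi: np.ndarray) -> np.ndarray:
    """Independent CLR oracle: explicit per-gene background loops."""
    n = mi.shape[0]
    z = np.zeros((n, n))
    for i in range(n):
        background = [mi[i, k] for k in range(n) if k != i]
        mu = np.mean(background)
        sd = np.std(background)  # population SD
        for j in range(n):
            if j == i or sd == 0:
                continue
            z[i, j] = max(0.0, (mi[i, j] - mu) / sd)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = np.sqrt(z[i, j] ** 2 + z[j, i] ** 2)
    return out


class TestMutualInformation:
    def test_identical_tiefree_profiles_give_ln_bins(self, rng):
        x = rng.normal(size=60)
        for bins in (2, 5, 10):
            assert mi_of_pair(x, x.copy(), bins) == pytest.approx(np.log(bins), rel=1e-12)

    def test_independent_shuffles_near_zero(self, rng):
        x = rng.permutation(1000).astype(float)
        y = rng.permutation(1000).astype(float)
        assert mi_of_pair(x, y, 10) <= 0.1

    def test_bivariate_normal_close_to_gaussian_closed_form(self):
        rng = np.random.default_rng(2024)
        rho, n = 0.9, 5000
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n).T
        target = -0.5 * np.log(1 - rho**2)
        assert abs(mi_of_pair(xy[0], xy[1], 10) - target) <= 0.12

    def test_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=80)
        y = x + rng.normal(scale=0.5, size=80)
        base = mi_of_pair(x, y, 8)
        assert mi_of_pair(np.exp(x), y, 8) == pytest.approx(base, abs=1e-12)
        assert mi_of_pair(x, y**3, 8) == pytest.approx(base, abs=1e-12)

    def test_symmetry_and_nonnegativity(self, rng):
        m = make_matrix(rng.normal(size=(12, 20)), kind="vst")
        mi = mutual_information(m, bins=4)
        off = ~np.eye(12, dtype=bool)
        assert np.allclose(mi.values, mi.values.T, equal_nan=True)
        assert (mi.values[off] >= 0).all()
        assert np.isnan(np.diag(mi.values)).all()

    def test_constant_profile_flagged_with_zero_mi(self, rng):
        arr = rng.normal(size=(3, 20))
        arr[1] = 2.5
        mi = mutual_information(make_matrix(arr, kind="vst"), bins=4)
        assert mi.constant_genes == ["g2"]
        assert mi.values[1, 0] == 0.0 and mi.values[1, 2] == 0.0

    def test_parameter_errors(self, rng):
        m = make_matrix(rng.normal(size=(2, 10)), kind="vst")
        with pytest.raises(ValueError, match="bins"):
            mutual_information(m, bins=11)
        with pytest.raises(ValueError, match="bins"):
            mutual_information(m, bins=1)
        with pytest.raises(ValueError, match="scheme"):
            mutual_information(m, bins=3, scheme="nope")
        small = make_matrix(rng.normal(size=(2, 5)), kind="vst")
        with pytest.raises(ValueError, match="samples"):
            mutual_information(small, bins=2)

    def test_default_bin_count_is_floor_sqrt(self, rng):
        m = make_matrix(rng.normal(size=(3, 51)), kind="vst")
        assert mutual_information(m).bins == 7

    @pytest.mark.parametrize("scheme", ["equal_width", "bspline"])
    def test_alternative_schemes_order_dependence_correctly(self, rng, scheme):
        x = rng.normal(size=400)
        y = x + rng.normal(scale=0.3, size=400)
        z = rng.normal(size=400)
        assert mi_of_pair(x, y, 8, scheme) > mi_of_pair(x, z, 8, scheme) + 0.2


class TestCLR:
    def test_flat_background_gives_zero(self):
        mi = np.full((4, 4), 0.3)
        np.fill_diagonal(mi, np.nan)
        clr = clr_transform(MIMatrix(list("abcd"), mi, 3, "equal_frequency"))
        assert (clr.values == 0).all()

    def test_three_gene_hand_example(self):
        mi = np.array([[np.nan, 0.2, 0.5], [0.2, np.nan, 0.8], [0.5, 0.8, np.nan]])
        clr = clr_transform(MIMatrix(["g1", "g2", "g3"], mi, 3, "equal_frequency"))
        # z_1(3) = (0.5-0.35)/0.15 = 1; z_3(1) rectified to 0 -> CLR = 1
        assert clr.values[0, 2] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            raw = rng.uniform(0, 1, size=(10, 10))
            mi = (raw + raw.T) / 2
            np.fill_diagonal(mi, np.nan)
            clr = clr_transform(MIMatrix([f"g{i}" for i in range(10)], mi, 3, "equal_frequency"))
            filled = np.nan_to_num(mi, nan=0.0)
            np.fill_diagonal(filled, 0.0)
            expected = brute_force_clr(np.where(np.isnan(mi), 0, mi))
            np.testing.assert_allclose(clr.values, expected, atol=1e-12)

    def test_invariant_to_constant_shift_of_all_entries(self, rng):
        raw = rng.uniform(0, 1, size=(8, 8))
        mi = (raw + raw.T) / 2
        np.fill_diagonal(mi, np.nan)
        genes = [f"g{i}" for i in range(8)]
        a = clr_transform(MIMatrix(genes, mi, 3, "equal_frequency"))
        b = clr_transform(MIMatrix(genes, mi + 0.7, 3, "equal_frequency"))
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_too_few_genes_rejected(self):
        mi = np.array([[np.nan, 0.1], [0.1, np.nan]])
        with pytest.raises(ValueError, match="3 genes"):
            clr_transform(MIMatrix(["a", "b"], mi, 2, "equal_frequency"))


def planted_ba_clr(seed=42, n=200, m=2, noise_p=0.15):
    """CLR scores where thresholding at 5 reveals a Barabasi-Albert graph."""
    rng = np.random.default_rng(seed)
    ba = nx.barabasi_albert_graph(n, m, seed=seed)
    vals = np.zeros((n, n))
    for u, v in ba.edges():
        s = rng.uniform(5.0, 6.0)
        vals[u, v] = vals[v, u] = s
    iu = np.triu_indices(n, 1)
    mask = (vals[iu] == 0) & (rng.random(iu[0].size) < noise_p)
    noise = rng.uniform(3.0, 5.0, size=mask.sum())
    vals[iu[0][mask], iu[1][mask]] = noise
    vals[iu[1][mask], iu[0][mask]] = noise
    return CLRMatrix([f"G{i:03d}" for i in range(n)], vals)


class TestThresholdSelection:
    def test_recovers_planted_ba_threshold(self):
        clr = planted_ba_clr()
        selected, report = select_threshold_scale_free(clr, [3.0, 4.0, 5.0, 6.0])
        assert selected == 5.0
        assert set(report.table["threshold"]) == {3.0, 4.0, 5.0, 6.0}
        assert (report.table.columns == ["threshold", "n_edges", "gamma", "r2"]).all()

    def test_tie_breaks_toward_smaller_threshold(self):
        clr = planted_ba_clr()
        # duplicated candidate: identical graphs, bitwise-equal fits
        selected, _ = select_threshold_scale_free(clr, [5.0, 5.0 + 0.0, 5.5])
        assert selected == 5.0

    def test_single_candidate_returned_with_report(self):
        clr = planted_ba_clr()
        selected, report = select_threshold_scale_free(clr, [5.0])
        assert selected == 5.0
        assert len(report.table) == 1

    def test_all_candidates_too_sparse_errors_with_counts(self):
        clr = planted_ba_clr()
        with pytest.raises(ValueError, match="edge counts"):
            select_threshold_scale_free(clr, [7.0, 8.0])


class TestBuildNetwork:
    def vst_and_clr(self, rng, n=6, s=20):
        arr = rng.normal(size=(n, s))
        m = make_matrix(arr, kind="vst")
        mi = mutual_information(m, bins=4)
        return m, clr_transform(mi)

    def test_threshold_above_max_gives_isolated_nodes(self, rng):
        m, clr = self.vst_and_clr(rng)
        net = build_network(m, clr, clr.values.max() + 1)
        assert net.n_edges == 0
        assert len(net.nodes) == 6

    def test_identical_profiles_positive_edge(self, rng):
        x = rng.normal(size=20)
        m = make_matrix(np.vstack([x, x, rng.normal(size=20)]), kind="vst")
        clr = clr_transform(mutual_information(m, bins=4))
        net = build_network(m, clr, 0.0)
        d = net.graph.edges["g1", "g2"]
        assert d["sign"] == "+" and d["pearson_r"] == pytest.approx(1.0)

    def test_negated_profile_negative_edge(self, rng):
        x = rng.normal(size=20)
        m = make_matrix(np.vstack([x, -x, rng.normal(size=20)]), kind="vst")
        clr = clr_transform(mutual_information(m, bins=4))
        net = build_network(m, clr, 0.0)
        d = net.graph.edges["g1", "g2"]
        assert d["sign"] == "-" and d["pearson_r"] == pytest.approx(-1.0)

    def test_edge_set_monotone_decreasing_in_threshold(self, rng):
        m, clr = self.vst_and_clr(rng, n=10)
        edges = {
            th: set(map(frozenset, build_network(m, clr, th).graph.edges))
            for th in (0.5, 1.0, 2.0)
        }
        assert edges[2.0] <= edges[1.0] <= edges[0.5]

    def test_gene_id_mismatch_named(self, rng):
        m, clr = self.vst_and_clr(rng)
        m2 = make_matrix(rng.normal(size=(6, 20)), genes=[f"x{i}" for i in range(6)], kind="vst")
        with pytest.raises(ValueError, match="x0"):
            build_network(m2, clr, 1.0)

    def test_every_edge_satisfies_threshold_and_sign_convention(self, rng):
        m, clr = self.vst_and_clr(rng, n=12)
        net = build_network(m, clr, 1.0)
        for u, v, d in net.graph.edges(data=True):
            assert d["clr_score"] >= 1.0
            assert d["sign"] == ("-" if d["pearson_r"] < 0 else "+")


class TestLargestSubnetwork:
    def from_edges(self, edges, nodes=()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            g.add_edge(u, v, clr_score=5.0, pearson_r=1.0, sign="+", zero_r=False)
        from xylemnet.network import CoexpressionNetwork

        return CoexpressionNetwork(g, 5.0)

    def test_larger_component_wins(self):
        net = self.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("x", "y"), ("y", "z")])
        sub = largest_subnetwork(net)
        assert set(sub.graph.nodes) == {"a", "b", "c", "d", "e"}

    def test_connected_network_is_identity(self):
        net = self.from_edges([("a", "b"), ("b", "c")])
        assert set(largest_subnetwork(net).graph.nodes) == {"a", "b", "c"}

    def test_size_tie_breaks_lexicographically(self):
        net = self.from_edges([("m", "n"), ("a", "b")])
        assert set(largest_subnetwork(net).graph.nodes) == {"a", "b"}

    def test_isolated_nodes_never_included(self):
        net = self.from_edges([("a", "b")], nodes=["iso1", "iso2"])
        assert set(largest_subnetwork(net).graph.nodes) == {"a", "b"}

    def test_edgeless_network_errors(self):
        net = self.from_edges([], nodes=["a", "b"])
        with pytest.raises(ValueError, match="no edges"):
            largest_subnetwork(net)

    def test_matches_bfs_component_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            g = nx.gnp_random_graph(n, 0.08, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            from xylemnet.network import CoexpressionNetwork

            gg = nx.Graph()
            gg.add_nodes_from(f"n{i}" for i in g.nodes)
            for u, v in g.edges:
                gg.add_edge(f"n{u}", f"n{v}", clr_score=5.0, pearson_r=0.5, sign="+", zero_r=False)
            sub = largest_subnetwork(CoexpressionNetwork(gg, 5.0))
            # BFS oracle
            seen, comps = set(), []
            for start in gg.nodes:
                if start in seen or gg.degree(start) == 0:
                    continue
                comp, frontier = {start}, [start]
                while frontier:
                    nxt = []
                    for u in frontier:
                        for v in gg.neighbors(u):
                            if v not in comp:
                                comp.add(v)
                                nxt.append(v)
                    frontier = nxt
                seen |= comp
                comps.append(comp)
            best = min(comps, key=lambda c: (-len(c), min(c)))
            assert set(sub.graph.nodes) == best


class TestPlantedModuleRecovery:
    def test_seed_target_edges_recovered_at_scale_free_threshold(self):
        # planted regulatory modules must be recovered at the threshold the
        # scale-freeness scan selects, under the two-species study conditions
        import xylemnet as xn

        cfg = xn.SimulationConfig(
            n_genes=500, peak_width=0.1, nb_dispersion=0.05, amplitude=1600.0, rng_seed=7
        )
        ma, _, truth = xn.simulate_species_pair(cfg, 5, 8, 0)
        sf = xn.compute_size_factors(ma)
        v = xn.vst_transform(ma, sf)
        ve = v.subset_genes(xn.filter_expressed(v))
        clr = clr_transform(mutual_information(ve))
        theta, _ = select_threshold_scale_free(clr, [3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0])
        net = build_network(ve, clr, theta)
        st_edges = {
            frozenset((s, t)) for s, tg in truth.seed_targets_a.items() for t in tg
        }
        module = {}
        for s, tg in truth.seed_targets_a.items():
            for g in {s} | tg:
                module[g] = s
        found = set(map(frozenset, net.graph.edges))
        recall = len(found & st_edges) / len(st_edges)
        true_pairs = {e for e in found if len({module.get(g) for g in e}) == 1 and None not in {module.get(g) for g in e}}
        precision = len(true_pairs) / len(found)
        assert recall >= 0.8
        assert precision >= 0.8
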