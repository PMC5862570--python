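"""Insulated diffusion kernel, exchanged heat, subnetworks, permutation test."""

import networkx as nx
import numpy as np
import pytest

import netheat as nh
from netheat.diffusion import InteractionNetwork, _strong_components


def _net(edges, threshold=400):
    return nh.build_network(edges, threshold)


def _ba_network(n=60, m=2, seed=4):
    g = nx.barabasi_albert_graph(n, m, seed=seed)
    edges = [(f"g{a:02d}", f"g{b:02d}", 500) for a, b in g.edges]
    return _net(edges)


class TestBuildNetwork:
    def test_all_below_threshold_errors(self):
        with pytest.raises(ValueError, match="threshold"):
            _net([("a", "b", 399)])

    def test_threshold_is_inclusive(self):
        net = _net([("a", "b", 400)])
        assert net.n_edges == 1

    def test_triangle_hand_filter(self):
        net = _net([("a", "b", 500), ("b", "c", 450), ("a", "c", 100)])
        assert net.n_edges == 2
        assert set(net.nodes) == {"a", "b", "c"}

    def test_self_loops_dropped(self):
        net = _net([("a", "a", 900), ("a", "b", 500)])
        assert net.n_edges == 1

    def test_duplicate_edges_keep_max_score(self):
        net = _net([("a", "b", 450), ("b", "a", 700)])
        assert net.edge_list() == [("a", "b", 700)]

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="combined score"):
            _net([("a", "b", 1500)])


class TestDiffusionKernel:
    def test_isolated_node_keeps_heat(self):
        g = nx.Graph()
        g.add_edge("a", "b", score=500)
        g.add_node("c")
        kern = nh.diffusion_kernel(InteractionNetwork(g, 400), beta=0.4)
        c = kern.nodes.index("c")
        assert kern.F[c, c] == 1.0

    def test_two_node_analytic_inverse(self):
        kern = nh.diffusion_kernel(_net([("a", "b", 500)]), beta=0.4)
        expected = np.array([[0.625, 0.375], [0.375, 0.625]])
        np.testing.assert_allclose(kern.F, expected, atol=1e-12)

    def test_columns_sum_to_one(self):
        kern = nh.diffusion_kernel(_ba_network(), beta=0.4)
        np.testing.assert_allclose(kern.F.sum(axis=0), 1.0, atol=1e-9)

    def test_matches_power_series_oracle(self):
        net = _ba_network(n=40)
        beta = 0.4
        kern = nh.diffusion_kernel(net, beta)
        A = nx.to_numpy_array(net.graph, nodelist=kern.nodes, weight=None)
        W = A / A.sum(axis=0, keepdims=True)
        series = np.zeros_like(W)
        term = beta * np.eye(W.shape[0])
        for _ in range(201):
            series += term
            term = (1 - beta) * (W @ term)
        np.testing.assert_allclose(kern.F, series, atol=1e-8)

    def test_bad_beta_rejected(self):
        with pytest.raises(ValueError):
            nh.diffusion_kernel(_net([("a", "b", 500)]), beta=1.0)


class TestExchangedHeat:
    def test_zero_heat_gives_zero_matrix(self):
        kern = nh.diffusion_kernel(_ba_network(), 0.4)
        E = nh.exchanged_heat(kern, np.zeros(len(kern.nodes)))
        assert not E.any()

    def test_single_hot_node_single_column(self):
        kern = nh.diffusion_kernel(_ba_network(), 0.4)
        h = np.zeros(len(kern.nodes))
        h[7] = 3.0
        E = nh.exchanged_heat(kern, h)
        nonzero_cols = np.flatnonzero(E.any(axis=0))
        assert list(nonzero_cols) == [7]

    def test_column_sums_conserve_heat(self, rng):
        kern = nh.diffusion_kernel(_ba_network(), 0.4)
        h = rng.random(len(kern.nodes))
        E = nh.exchanged_heat(kern, h)
        np.testing.assert_allclose(E.sum(axis=0), h, atol=1e-9)

    def test_negative_heat_rejected(self):
        kern = nh.diffusion_kernel(_net([("a", "b", 500)]), 0.4)
        with pytest.raises(ValueError, match="nonnegative"):
            nh.exchanged_heat(kern, np.array([-1.0, 1.0]))


class TestExtractSubnetworks:
    def test_delta_above_max_gives_nothing(self):
        kern = nh.diffusion_kernel(_ba_network(), 0.4)
        E = nh.exchanged_heat(kern, np.ones(len(kern.nodes)))
        assert nh.extract_subnetworks(E, E.max() + 1, kern.nodes) == []

    def test_two_node_symmetric_exchange(self):
        kern = nh.diffusion_kernel(_net([("a", "b", 500)]), 0.4)
        E = nh.exchanged_heat(kern, np.array([2.0, 2.0]))
        subs = nh.extract_subnetworks(E, delta=E[0, 1] / 2, nodes=kern.nodes, min_size=2)
        assert len(subs) == 1
        assert subs[0].genes == ["a", "b"]

    def test_components_match_networkx_oracle(self, rng):
        kern = nh.diffusion_kernel(_ba_network(n=50, seed=9), 0.4)
        h = rng.random(len(kern.nodes)) * 3
        E = nh.exchanged_heat(kern, h)
        delta = float(np.quantile(E[E > 0], 0.95))
        subs = nh.extract_subnetworks(E, delta, kern.nodes, min_size=2)
        # independent reachability oracle
        dg = nx.DiGraph()
        dg.add_nodes_from(range(len(kern.nodes)))
        for i in range(E.shape[0]):
            for j in range(E.shape[1]):
                if i != j and E[i, j] >= delta:
                    dg.add_edge(j, i)
        expected = sorted(
            (sorted(kern.nodes[i] for i in c)
             for c in nx.strongly_connected_components(dg) if len(c) >= 2),
            key=lambda gs: (-len(gs), gs),
        )
        assert [s.genes for s in subs] == expected
        flat = [g for s in subs for g in s.genes]
        assert len(flat) == len(set(flat))  # pairwise disjoint

    def test_raising_delta_never_enlarges_components(self, rng):
        kern = nh.diffusion_kernel(_ba_network(n=40, seed=2), 0.4)
        h = rng.random(len(kern.nodes)) * 2
        E = nh.exchanged_heat(kern, h)
        grid = np.quantile(E[E > 0], [0.5, 0.7, 0.9, 0.99])
        maxes = [
            max((s.size for s in nh.extract_subnetworks(E, d, kern.nodes, 2)), default=1)
            for d in grid
        ]
        assert maxes == sorted(maxes, reverse=True)


class TestPermutationSignificance:
    def test_constant_heat_is_null_typical(self):
        net = _ba_network(n=40, seed=3)
        kern = nh.diffusion_kernel(net, 0.4)
        h = np.ones(len(kern.nodes))
        E = nh.exchanged_heat(kern, h)
        delta = float(np.quantile(E[E > 0], 0.8))
        hits = 0
        for seed in range(10):
            rep = nh.permutation_significance(net, h, delta, n_perm=49, seed=seed, kernel=kern)
            if (rep.table["p"] > 0.05).all():
                hits += 1
        assert hits >= 9  # constant heat is exchangeable: permutations identical

    def test_add_one_floor(self, rng):
        net = _ba_network(n=40, seed=5)
        kern = nh.diffusion_kernel(net, 0.4)
        h = rng.random(len(kern.nodes)) * 3
        E = nh.exchanged_heat(kern, h)
        rep = nh.permutation_significance(
            net, h, float(np.quantile(E[E > 0], 0.9)), n_perm=49, seed=1, kernel=kern
        )
        assert (rep.table["p"] >= 1 / 50).all()
        assert (rep.table["p"] <= 1.0).all()

    def test_deterministic_given_seed(self, rng):
        net = _ba_network(n=30, seed=6)
        kern = nh.diffusion_kernel(net, 0.4)
        h = rng.random(len(kern.nodes))
        a = nh.permutation_significance(net, h, 0.01, n_perm=25, seed=42, kernel=kern)
        b = nh.permutation_significance(net, h, 0.01, n_perm=25, seed=42, kernel=kern)
        assert a.table.equals(b.table)

    def test_too_few_permutations_rejected(self):
        net = _net([("a", "b", 500)])
        with pytest.raises(ValueError):
            nh.permutation_significance(net, np.array([1.0, 0.0]), 0.1, n_perm=5)


class TestChooseDelta:
    def test_single_edge_hand_trace(self):
        # two nodes, heats (h, 0): permuted E has one positive off-diagonal
        # value v = F12 * h; the largest component is never >= target, so the
        # binary search bottoms out at the smallest grid value v itself
        net = _net([("a", "b", 500)])
        kern = nh.diffusion_kernel(net, 0.4)
        h = np.array([4.0, 0.0])
        delta = nh.choose_delta(net, h, n_perm=19, target_max_size=2, seed=0, kernel=kern)
        v_candidates = {0.375 * 4.0, 0.625 * 4.0}  # off-diag and diag never mix
        assert delta == pytest.approx(0.375 * 4.0)
        assert any(delta == pytest.approx(v) for v in v_candidates)

    def test_deterministic_given_seed(self, rng):
        net = _ba_network(n=30, seed=8)
        kern = nh.diffusion_kernel(net, 0.4)
        h = rng.random(len(kern.nodes)) * 2
        d1 = nh.choose_delta(net, h, n_perm=19, seed=3, kernel=kern)
        d2 = nh.choose_delta(net, h, n_perm=19, seed=3, kernel=kern)
        assert d1 == d2

    def test_delta_on_permuted_value_grid(self, rng):
        net = _ba_network(n=25, seed=12)
        kern = nh.diffusion_kernel(net, 0.4)
        h = rng.random(len(kern.nodes)) * 2
        delta = nh.choose_delta(net, h, n_perm=19, target_max_size=5, seed=7, kernel=kern)
        all_values = set()
        gen = np.random.default_rng(7)
        for _ in range(19):
            E = nh.exchanged_heat(kern, gen.permutation(h))
            off = E[~np.eye(E.shape[0], dtype=bool)]
            all_values.update(np.unique(off[off > 0]))
            all_values.update(np.nextafter(v, np.inf) for v in all_values.copy())
        assert any(delta == pytest.approx(v, rel=1e-12) for v in all_values)

    def test_all_zero_heat_rejected(self):
        net = _net([("a", "b", 500)])
        with pytest.raises(ValueError, match="all zero"):
            nh.choose_delta(net, np.zeros(2), n_perm=19, seed=0)


class TestSignificantSubnetworks:
    def test_reports_tightest_significant_scale(self):
        import pandas as pd

        subs = [nh.Subnetwork(1, list("abcdefgh"), 8), nh.Subnetwork(2, list("xyz"), 3)]
        table = pd.DataFrame(
            {"size_threshold": [2, 3, 8], "observed": [2, 2, 1],
             "expected": [1.5, 0.8, 0.05], "p": [0.5, 0.2, 0.01]}
        )
        rep = nh.SignificanceReport(delta=0.1, table=table, n_perm=100)
        out = nh.significant_subnetworks(subs, rep)
        assert [s.index for s in out] == [1]

    def test_empty_when_nothing_significant(self):
        import pandas as pd

        subs = [nh.Subnetwork(1, list("abc"), 3)]
        table = pd.DataFrame(
            {"size_threshold": [2, 3], "observed": [1, 1],
             "expected": [1.2, 0.9], "p": [0.7, 0.4]}
        )
        rep = nh.SignificanceReport(delta=0.1, table=table, n_perm=100)
        assert nh.significant_subnetworks(subs, rep) == []
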