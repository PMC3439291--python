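"""Correlation networks, k-core decomposition, DiffK, permutation null."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recurnet.coexnet import (
    build_group_networks,
    build_network,
    connectivity,
    correlation_matrix,
    diffk,
    kcore_decompose,
    permutation_significance,
    significant_pairs,
)
from recurnet.synthetic import ModuleSpec, SimulationConfig, generate_expression

from conftest import make_expr


def edges_frame(pairs):
    return pd.DataFrame(
        [(a, b, 0.9, 0.001) for a, b in pairs],
        columns=["gene_a", "gene_b", "r", "p"],
    )


def brute_force_core_numbers(g: nx.Graph) -> dict:
    """Oracle: for every k independently, strip nodes of degree < k until
    stable; a node's core number is the largest k it survives."""
    core = {v: 0 for v in g.nodes}
    maxdeg = max((d for _, d in g.degree()), default=0)
    for k in range(1, maxdeg + 1):
        h = g.copy()
        while True:
            drop = [v for v, d in h.degree() if d < k]
            if not drop:
                break
            h.remove_nodes_from(drop)
        for v in h.nodes:
            core[v] = k
    return core


class TestCorrelationMatrix:
    def test_copy_and_negation(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        x = np.vstack([base, base * 3 + 1, -base, rng.normal(size=10)])
        expr = make_expr(np.hstack([x, rng.normal(size=(4, 5))]), 10, 5)
        corr = correlation_matrix(expr, "recurrence")
        def get(a, b):
            row = corr[(corr["gene_a"] == a) & (corr["gene_b"] == b)]
            return float(row["r"].iloc[0])
        assert get("G0000", "G0001") == pytest.approx(1.0)
        assert get("G0000", "G0002") == pytest.approx(-1.0)

    def test_too_few_samples_rejected(self):
        expr = make_expr(np.random.default_rng(1).normal(size=(5, 4)), 2, 2)
        with pytest.raises(ValueError):
            correlation_matrix(expr, "recurrence")

    def test_null_rejection_rate_at_1pct(self):
        """Among null pairs, |r| crosses the 1%-level critical value about 1%
        of the time."""
        rng = np.random.default_rng(2)
        expr = make_expr(rng.normal(size=(200, 110)), 100, 10)
        corr = correlation_matrix(expr, "recurrence")
        frac = (corr["p"] < 0.01).mean()
        n_pairs = len(corr)  # 19900 non-independent pairs; generous band
        assert 0.005 <= frac <= 0.02

    def test_constant_gene_flagged(self):
        x = np.random.default_rng(3).normal(size=(4, 8))
        x[1] = 5.0
        expr = make_expr(x, 5, 3)
        corr = correlation_matrix(expr, "recurrence")
        flagged = corr[(corr["gene_a"] == "G0001") | (corr["gene_b"] == "G0001")]
        assert (~flagged["defined"]).all()
        assert (flagged["p"] == 1.0).all()


class TestSignificantPairs:
    def test_extreme_pair_kept_weak_pair_dropped(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=10)
        x = np.vstack([base, base + rng.normal(0, 0.05, 10), rng.normal(size=10)])
        expr = make_expr(np.hstack([x, rng.normal(size=(3, 3))]), 10, 3)
        corr = correlation_matrix(expr, "recurrence")
        edges = significant_pairs(corr)
        kept = set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy()))
        assert ("G0000", "G0001") in kept
        assert ("G0000", "G0002") not in kept

    def test_null_retained_fraction_with_p_gate_only(self):
        rng = np.random.default_rng(5)
        expr = make_expr(rng.normal(size=(65, 43)), 40, 3)
        corr = correlation_matrix(expr, "recurrence")  # 2080 pairs
        edges = significant_pairs(corr, p_max=0.05, min_abs_r=0.0)
        assert len(edges) / len(corr) == pytest.approx(0.05, abs=0.02)

    def test_empty_result_warns(self):
        rng = np.random.default_rng(6)
        expr = make_expr(rng.normal(size=(5, 13)), 10, 3)
        corr = correlation_matrix(expr, "recurrence")
        with pytest.warns(UserWarning):
            edges = significant_pairs(corr, p_max=1e-12, min_abs_r=0.999)
        assert edges.empty


class TestBuildNetworkAndConnectivity:
    def test_isolated_nodes_kept(self):
        net = build_network(edges_frame([]), [f"n{i}" for i in range(5)])
        assert len(net.nodes) == 5 and net.n_edges == 0
        assert all(k == 0 for k in connectivity(net).values())

    def test_triangle_degrees(self):
        net = build_network(edges_frame([("a", "b"), ("b", "c"), ("a", "c")]),
                            ["a", "b", "c"])
        assert connectivity(net) == {"a": 2, "b": 2, "c": 2}

    def test_star_and_complete(self):
        leaves = [f"l{i}" for i in range(6)]
        star = build_network(edges_frame([("hub", l) for l in leaves]),
                             ["hub"] + leaves)
        k = connectivity(star)
        assert k["hub"] == 6 and all(k[l] == 1 for l in leaves)
        k4 = build_network(
            edges_frame([("a", "b"), ("a", "c"), ("a", "d"),
                         ("b", "c"), ("b", "d"), ("c", "d")]),
            list("abcd"))
        assert set(connectivity(k4).values()) == {3}

    def test_handshake_identity_on_random_graph(self):
        g = nx.gnp_random_graph(40, 0.15, seed=7)
        net = build_network(edges_frame(list(g.edges)), list(g.nodes))
        assert sum(connectivity(net).values()) == 2 * net.n_edges

    def test_duplicate_conflicting_edge_rejected(self):
        edges = pd.DataFrame(
            [("a", "b", 0.9, 0.001), ("b", "a", -0.5, 0.001)],
            columns=["gene_a", "gene_b", "r", "p"],
        )
        with pytest.raises(ValueError):
            build_network(edges, ["a", "b"])

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError):
            build_network(edges_frame([("a", "a")]), ["a"])

    def test_edge_round_trip(self, tmp_path):
        from recurnet.io import read_edges, write_edges
        g = nx.gnp_random_graph(15, 0.3, seed=8)
        pairs = [(f"g{a}", f"g{b}") for a, b in g.edges]
        nodes = [f"g{v}" for v in g.nodes]
        net = build_network(edges_frame(pairs), nodes)
        write_edges(edges_frame(pairs), "recurrence", tmp_path / "e.tsv")
        back = build_network(read_edges(tmp_path / "e.tsv"), nodes)
        assert nx.utils.graphs_equal(net.graph, back.graph)


class TestKCore:
    def test_triangle_plus_pendant(self):
        net = build_network(
            edges_frame([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")]),
            list("abcd"))
        core, max_sub = kcore_decompose(net)
        assert core == {"a": 2, "b": 2, "c": 2, "d": 1}
        assert set(max_sub.nodes) == {"a", "b", "c"}

    def test_complete_graph(self):
        k4 = build_network(
            edges_frame([("a", "b"), ("a", "c"), ("a", "d"),
                         ("b", "c"), ("b", "d"), ("c", "d")]),
            list("abcd"))
        core, max_sub = kcore_decompose(k4)
        assert set(core.values()) == {3}
        assert set(max_sub.nodes) == set("abcd")

    def test_matches_brute_force_and_networkx(self):
        rng = np.random.default_rng(9)
        for _ in range(60):
            n = int(rng.integers(2, 40))
            p = float(rng.uniform(0.02, 0.35))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {v: f"n{v:02d}" for v in g.nodes})
            net = build_network(edges_frame(list(g.edges)), list(g.nodes))
            core, _ = kcore_decompose(net)
            assert core == brute_force_core_numbers(g)
            assert core == nx.core_number(g)


class TestDiffK:
    def test_identical_networks_give_zero(self):
        g = nx.gnp_random_graph(20, 0.3, seed=10)
        pairs = [(f"g{a}", f"g{b}") for a, b in g.edges]
        nodes = [f"g{v}" for v in g.nodes]
        net = build_network(edges_frame(pairs), nodes)
        res = diffk(net, net)
        assert np.allclose(res.table["diffk"], 0.0)

    def test_bound_attained_by_exclusive_hub(self):
        net1 = build_network(edges_frame([("hub", f"l{i}") for i in range(5)]),
                             ["hub"] + [f"l{i}" for i in range(5)] + ["x", "y"])
        net2 = build_network(edges_frame([("x", "y")]),
                             ["hub"] + [f"l{i}" for i in range(5)] + ["x", "y"])
        res = diffk(net1, net2)
        assert res.table.loc["hub", "diffk"] == pytest.approx(1.0)
        assert res.table.loc["hub", "rank"] == 1

    def test_antisymmetry_and_bounds(self):
        rng = np.random.default_rng(11)
        g1 = nx.gnp_random_graph(30, 0.2, seed=12)
        g2 = nx.gnp_random_graph(30, 0.2, seed=13)
        nodes = [f"g{v}" for v in range(30)]
        n1 = build_network(edges_frame([(f"g{a}", f"g{b}") for a, b in g1.edges]), nodes)
        n2 = build_network(edges_frame([(f"g{a}", f"g{b}") for a, b in g2.edges]), nodes)
        fwd = diffk(n1, n2).table["diffk"]
        rev = diffk(n2, n1).table["diffk"]
        assert np.allclose(fwd, -rev.loc[fwd.index])
        assert fwd.between(-1, 1).all()
        assert fwd.loc[fwd.abs().idxmax()] == pytest.approx(
            fwd.abs().max() * np.sign(fwd.loc[fwd.abs().idxmax()]))

    def test_max_degree_zero_raises(self):
        nodes = ["a", "b", "c"]
        full = build_network(edges_frame([("a", "b")]), nodes)
        empty = build_network(edges_frame([]), nodes)
        with pytest.raises(ValueError, match="maximum degree 0"):
            diffk(full, empty)

    def test_planted_hubs_rank_in_top_5pct(self, module_expr_40v40):
        expr = module_expr_40v40
        net1, net2 = build_group_networks(expr, "recurrence", "non-recurrence")
        res = diffk(net1, net2)
        hubs = expr.truth.hub_genes[0]
        cut = int(0.05 * len(res.table))
        top = set(res.table.index[res.table["rank"] <= cut])
        assert len(hubs & top) / len(hubs) >= 0.9


class TestPermutationSignificance:
    def test_p_never_zero_and_granularity_warning(self, module_expr_40v40):
        with pytest.warns(UserWarning, match="granularity"):
            res = permutation_significance(
                module_expr_40v40.subset_genes(module_expr_40v40.gene_ids[:60]),
                "recurrence", "non-recurrence", n_perm=99, seed=1)
        assert (res["p_perm"] > 0).all()
        assert res["p_perm"].min() >= 1 / 100

    def test_null_p_uniform(self):
        cfg = SimulationConfig(n_genes=100, n_recurrence=20, n_nonrecurrence=20,
                               n_de_up=1, n_de_down=1, de_effect=0.0,
                               module_specs=(), seed=9)
        expr = generate_expression(cfg)
        res = permutation_significance(expr, "recurrence", "non-recurrence",
                                       n_perm=199, seed=9, p_max=0.05,
                                       min_abs_r=0.0)
        ks = stats.kstest(res["p_perm"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_hub_p_small(self):
        cfg = SimulationConfig(n_genes=100, n_recurrence=80, n_nonrecurrence=80,
                               n_de_up=1, n_de_down=1, de_effect=0.0,
                               module_specs=(ModuleSpec(10, 3, 0.9, 0.0),
                                             ModuleSpec(10, 3, 0.0, 0.9)),
                               seed=13)
        expr = generate_expression(cfg)
        res = permutation_significance(expr, "recurrence", "non-recurrence",
                                       n_perm=100, seed=13)
        hubs = sorted(expr.truth.hub_genes[0])
        assert (res.loc[hubs, "p_perm"] <= 0.02).all()
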