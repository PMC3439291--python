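"""Per-group Pearson co-expression networks, k-core decomposition, and
differential connectivity (DiffK).

Two networks are built over the same gene set — network 1 from the recurrence
samples, network 2 from the non-recurrence samples — by keeping gene pairs
whose Pearson correlation is both significant (p < p_max from the t-transform
of r) and strong (|r| >= min_abs_r).  Connectivity k(i) is plain degree
centrality; within each network it is normalized by the maximum degree,
K(i) = k(i) / max k, and the differential connectivity of gene i is

    DiffK(i) = K1(i) - K2(i)  in [-1, 1].

Genes more connected in the recurrence network get positive DiffK; ranking is
by signed descending DiffK (an |DiffK| ranking is reported alongside).  The
k-core decomposition (iterative pruning of nodes with degree < k) summarizes
the dense modules of each network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import LabeledExpressionMatrix

DEFAULT_P_MAX = 0.05
DEFAULT_MIN_ABS_R = 0.7


def correlation_matrix(
    expr: LabeledExpressionMatrix, group: str
) -> pd.DataFrame:
    """Pearson r and p for every unordered gene pair within one group.

    p comes from the exact t-transform t = r sqrt((m-2)/(1-r^2)) with m-2
    degrees of freedom (m = samples in the group).  Constant genes have
    undefined correlation; their pairs are returned with r = NaN and p = 1 and
    flagged in the ``defined`` column.
    """
    samples = expr.samples_in(group)
    m = len(samples)
    if m < 3:
        raise ValueError(
            f"group {group!r} has {m} samples; need >= 3 for a correlation p-value"
        )
    x = expr.values[samples].to_numpy(float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    sd = x.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    iu, ju = np.triu_indices(x.shape[0], k=1)
    rv = r[iu, ju]
    defined = ~(constant[iu] | constant[ju])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rv * np.sqrt((m - 2) / np.maximum(1.0 - rv**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), m - 2)
    p = np.where(defined, p, 1.0)
    rv = np.where(defined, rv, np.nan)
    genes = np.asarray(expr.gene_ids)
    out = pd.DataFrame(
        {
            "gene_a": genes[iu],
            "gene_b": genes[ju],
            "r": rv,
            "p": p,
            "defined": defined,
        }
    )
    return out


def significant_pairs(
    corr: pd.DataFrame,
    p_max: float = DEFAULT_P_MAX,
    min_abs_r: float = DEFAULT_MIN_ABS_R,
) -> pd.DataFrame:
    """Edge list: pairs with p < p_max AND |r| >= min_abs_r."""
    keep = (
        corr["defined"]
        & (corr["p"] < p_max)
        & (corr["r"].abs() >= min_abs_r)
    )
    edges = corr.loc[keep, ["gene_a", "gene_b", "r", "p"]].reset_index(drop=True)
    if edges.empty:
        warnings.warn(
            "no gene pair met the correlation criteria "
            f"(p < {p_max}, |r| >= {min_abs_r}); the network will be edgeless"
        )
    return edges


@dataclass
class CoexpressionNetwork:
    """Simple undirected gene graph with per-edge r and p."""

    graph: nx.Graph
    group_label: str

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())


def build_network(
    edges: pd.DataFrame, nodes, group_label: str = ""
) -> CoexpressionNetwork:
    """Assemble the network; isolated nodes are kept with degree 0."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    node_set = set(g.nodes)
    for row in edges.itertuples(index=False):
        a, b = row.gene_a, row.gene_b
        if a == b:
            raise ValueError(f"self-edge on {a}")
        if a not in node_set or b not in node_set:
            raise ValueError(f"edge ({a}, {b}) references unknown node")
        if g.has_edge(a, b) and not np.isclose(g[a][b]["r"], row.r):
            raise ValueError(f"duplicate edge ({a}, {b}) with conflicting r")
        g.add_edge(a, b, r=float(row.r), p=float(row.p))
    return CoexpressionNetwork(graph=g, group_label=group_label)


def write_graphml(net: CoexpressionNetwork, path) -> None:
    """Export for network viewers (Cytoscape, Gephi); edge r and p are kept
    as attributes."""
    g = net.graph.copy()
    g.graph["group"] = net.group_label
    nx.write_graphml(g, path)


def connectivity(net: CoexpressionNetwork) -> dict[str, int]:
    """Whole-network connectivity k(i): the degree of each gene."""
    return net.degrees()


def kcore_decompose(
    net: CoexpressionNetwork,
) -> tuple[dict[str, int], nx.Graph]:
    """Core number per gene by iterative pruning, plus the max-core subgraph.

    Repeatedly removing all nodes of degree < k leaves the k-core; a node's
    core number is the largest k at which it survives.  Implemented as the
    standard peeling: repeatedly delete a minimum-degree node, recording the
    running maximum of the minimum degree seen at deletion time.
    """
    deg = dict(net.graph.degree())
    core: dict[str, int] = {}
    neighbors = {v: set(net.graph[v]) for v in net.graph}
    remaining = set(deg)
    k = 0
    while remaining:
        v = min(remaining, key=lambda u: (deg[u], u))
        k = max(k, deg[v])
        core[v] = k
        remaining.discard(v)
        for u in neighbors[v]:
            if u in remaining:
                deg[u] -= 1
                neighbors[u].discard(v)
    max_core = max(core.values(), default=0)
    keep = [v for v, c in core.items() if c == max_core]
    return core, net.graph.subgraph(keep).copy()


@dataclass
class ConnectivityTable:
    """Per-gene connectivity comparison between the two networks.

    ``table`` columns: k1, k2, K1, K2, diffk, rank (signed descending DiffK),
    rank_abs (descending |DiffK|), core1, core2.
    """

    table: pd.DataFrame
    group1: str
    group2: str


def diffk(
    net1: CoexpressionNetwork, net2: CoexpressionNetwork
) -> ConnectivityTable:
    """Differential connectivity DiffK(i) = K1(i) - K2(i) over the node union.

    Genes absent from one network count as degree 0 there.  Ties in the
    ranking break by descending k1, then lexical gene ID.
    """
    nodes = sorted(set(net1.nodes) | set(net2.nodes))
    d1, d2 = net1.degrees(), net2.degrees()
    k1 = np.array([d1.get(g, 0) for g in nodes], dtype=float)
    k2 = np.array([d2.get(g, 0) for g in nodes], dtype=float)
    if k1.max() == 0 or k2.max() == 0:
        raise ValueError(
            "cannot normalize connectivity: a network has maximum degree 0 "
            f"(max k1={int(k1.max())}, max k2={int(k2.max())}); relax the "
            "edge criteria or check the input"
        )
    K1 = k1 / k1.max()
    K2 = k2 / k2.max()
    core1, _ = kcore_decompose(net1)
    core2, _ = kcore_decompose(net2)
    out = pd.DataFrame(
        {
            "k1": k1.astype(int),
            "k2": k2.astype(int),
            "K1": K1,
            "K2": K2,
            "diffk": K1 - K2,
            "core1": [core1.get(g, 0) for g in nodes],
            "core2": [core2.get(g, 0) for g in nodes],
        },
        index=pd.Index(nodes, name="gene_id"),
    )
    order = out.sort_values(
        ["diffk", "k1"], ascending=[False, False], kind="mergesort"
    ).index
    out.loc[order, "rank"] = np.arange(1, len(out) + 1)
    out["abs_diffk"] = out["diffk"].abs()
    order_abs = out.sort_values(
        ["abs_diffk", "k1"], ascending=[False, False], kind="mergesort"
    ).index
    out.loc[order_abs, "rank_abs"] = np.arange(1, len(out) + 1)
    out = out.drop(columns="abs_diffk")
    out["rank"] = out["rank"].astype(int)
    out["rank_abs"] = out["rank_abs"].astype(int)
    return ConnectivityTable(
        table=out.sort_values("rank"), group1=net1.group_label, group2=net2.group_label
    )


def build_group_networks(
    expr: LabeledExpressionMatrix,
    group1: str,
    group2: str,
    p_max: float = DEFAULT_P_MAX,
    min_abs_r: float = DEFAULT_MIN_ABS_R,
) -> tuple[CoexpressionNetwork, CoexpressionNetwork]:
    """Convenience: both per-group networks from one expression matrix."""
    nets = []
    for group in (group1, group2):
        corr = correlation_matrix(expr, group)
        edges = significant_pairs(corr, p_max=p_max, min_abs_r=min_abs_r)
        nets.append(build_network(edges, expr.gene_ids, group_label=group))
    return nets[0], nets[1]


def _diffk_values(
    x: np.ndarray,
    genes: list[str],
    mask1: np.ndarray,
    mask2: np.ndarray,
    p_max: float,
    min_abs_r: float,
) -> np.ndarray:
    """Vectorized DiffK on a raw array, used by the permutation null."""
    n_genes = x.shape[0]
    ks = []
    for mask in (mask1, mask2):
        xm = x[:, mask]
        m = xm.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(xm)
        np.clip(r, -1.0, 1.0, out=r)
        np.fill_diagonal(r, 0.0)
        t = r * np.sqrt((m - 2) / np.maximum(1.0 - r**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), m - 2)
        adj = (p < p_max) & (np.abs(r) >= min_abs_r)
        ks.append(adj.sum(axis=1).astype(float))
    k1, k2 = ks
    if k1.max() == 0 or k2.max() == 0:
        raise ValueError("a permuted network has maximum degree 0")
    return k1 / k1.max() - k2 / k2.max()


def permutation_significance(
    expr: LabeledExpressionMatrix,
    group1: str,
    group2: str,
    n_perm: int = 200,
    seed: int = 0,
    p_max: float = DEFAULT_P_MAX,
    min_abs_r: float = DEFAULT_MIN_ABS_R,
) -> pd.DataFrame:
    """Empirical two-sided per-gene p-values for DiffK by label permutation.

    Group labels are shuffled between the two groups, the full
    correlation -> threshold -> degree -> DiffK pipeline is re-run per
    permutation, and p(i) = (1 + #{perm: |DiffK*(i)| >= |DiffK(i)|}) /
    (n_perm + 1) — never exactly 0 by the add-one rule.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives p-value granularity 1/{n_perm + 1}; "
            "consider n_perm >= 100"
        )
    s1, s2 = expr.samples_in(group1), expr.samples_in(group2)
    samples = s1 + s2
    x = expr.values[samples].to_numpy(float)
    n1 = len(s1)
    mask1 = np.zeros(len(samples), dtype=bool)
    mask1[:n1] = True
    observed = _diffk_values(
        x, expr.gene_ids, mask1, ~mask1, p_max, min_abs_r
    )
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = rng.permutation(len(samples))
        pm1 = np.zeros(len(samples), dtype=bool)
        pm1[perm[:n1]] = True
        try:
            star = _diffk_values(x, expr.gene_ids, pm1, ~pm1, p_max, min_abs_r)
        except ValueError:
            # an edgeless permuted network contributes DiffK* = 0 everywhere
            star = np.zeros_like(observed)
        exceed += np.abs(star) >= np.abs(observed)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return pd.DataFrame(
        {"diffk": observed, "p_perm": p},
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )
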