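"""Co-occurrence network construction, module detection and topology metrics.

Edges connect ASV pairs whose Spearman correlation across samples is strong
(|rho| above a threshold, 0.75 by default) and significant after
Benjamini–Hochberg control of the false discovery rate (adjusted p below
0.001 by default).  Edge weights keep the sign of the correlation; module
detection and all topology metrics operate on the unweighted graph.  Nodes
with no surviving edge are not part of the network.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "prevalence_filter",
    "spearman_matrix",
    "bh_adjust",
    "build_network",
    "correlation_network",
    "detect_modules",
    "modularity",
    "avg_clustering",
    "avg_path_length",
    "degree_centralization",
    "topology_report",
    "module_abundance",
]


def prevalence_filter(table: pd.DataFrame, min_samples: int = 5) -> pd.DataFrame:
    """Retain ASVs present (count > 0) in at least ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    prevalence = (table > 0).sum(axis=0)
    return table.loc[:, prevalence >= min_samples]


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho among ASVs with two-sided t-approximation p-values.

    Ties receive average ranks.  Constant ASV columns have undefined
    correlations; their entries are NaN and yield no edges downstream.
    """
    if table.shape[0] < 4:
        raise ValueError(f"need >= 4 samples for correlations, got {table.shape[0]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p = stats.spearmanr(table.to_numpy(dtype=float), axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the two-variable case to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[np.nan, p], [p, np.nan]])
    else:
        rho = np.atleast_2d(rho)
        p = np.atleast_2d(p)
    ids = table.columns
    return (
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_network(
    rho: pd.DataFrame,
    p_adj: pd.DataFrame,
    r_threshold: float = 0.75,
    p_threshold: float = 0.001,
) -> nx.Graph:
    """Threshold the correlation matrix into a signed undirected network.

    Edge (i, j) exists iff |rho_ij| > r_threshold and p_adj_ij < p_threshold.
    Edge attributes: ``weight`` (signed rho) and ``p_adj``.  Isolated ASVs are
    excluded.  The edge set does not depend on row/column ordering.
    """
    if not (0 < r_threshold < 1 and 0 < p_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if rho.shape != p_adj.shape:
        raise ValueError("rho and p_adj matrices must be conformable")
    ids = sorted(rho.index)
    g = nx.Graph()
    for a, i in [(ids[k], k) for k in range(len(ids))]:
        for b in ids[i + 1 :]:
            r = rho.loc[a, b]
            q = p_adj.loc[a, b]
            if np.isnan(r) or np.isnan(q):
                continue
            if abs(r) > r_threshold and q < p_threshold:
                g.add_edge(a, b, weight=float(r), p_adj=float(q))
    return g


def correlation_network(
    table: pd.DataFrame,
    r_threshold: float = 0.75,
    p_threshold: float = 0.001,
    min_samples: int = 5,
) -> nx.Graph:
    """Prevalence-filter, correlate, BH-adjust, threshold: the full edge path."""
    filtered = prevalence_filter(table, min_samples)
    rho, p = spearman_matrix(filtered)
    iu = np.triu_indices(rho.shape[0], k=1)
    flat_p = p.to_numpy()[iu]
    valid = ~np.isnan(flat_p)
    adj = np.full_like(flat_p, np.nan)
    if valid.any():
        adj[valid] = bh_adjust(flat_p[valid])
    q = np.full(rho.shape, np.nan)
    q[iu] = adj
    q.T[iu] = adj
    p_adj = pd.DataFrame(q, index=rho.index, columns=rho.columns)
    return build_network(rho, p_adj, r_threshold, p_threshold)


def detect_modules(net: nx.Graph, seed: int = 0) -> dict:
    """Partition the network into modules by seeded modularity maximization.

    Greedy local moves with agglomeration (Louvain) on the unweighted graph;
    deterministic for a given seed.  Modules are labeled 1, 2, ... in
    decreasing node-count order (ties broken by smallest member name), so
    "module 1" is always the largest.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    communities = nx.community.louvain_communities(net, weight=None, seed=seed)
    ordered = sorted(communities, key=lambda c: (-len(c), min(map(str, c))))
    return {node: label for label, comm in enumerate(ordered, start=1) for node in comm}


def modularity(net: nx.Graph, partition: dict) -> float:
    """Newman–Girvan modularity Q of a partition on the unweighted graph."""
    if net.number_of_edges() == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    if set(partition) != set(net.nodes):
        raise ValueError("partition must cover exactly the network nodes")
    groups: dict = {}
    for node, label in partition.items():
        groups.setdefault(label, set()).add(node)
    return float(nx.community.modularity(net, groups.values(), weight=None))


def avg_clustering(net: nx.Graph) -> float:
    """Mean local clustering coefficient; degree-<2 nodes contribute 0."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    return float(nx.average_clustering(net))


def avg_path_length(net: nx.Graph) -> float:
    """Mean shortest-path length over connected ordered pairs (unweighted).

    Pairs in different components are excluded rather than given an infinite
    length, so disconnected networks still report a finite value.
    """
    if net.number_of_edges() == 0:
        raise ValueError("average path length undefined without edges")
    total = 0.0
    pairs = 0
    for comp in nx.connected_components(net):
        n = len(comp)
        if n < 2:
            continue
        sub = net.subgraph(comp)
        total += nx.average_shortest_path_length(sub) * n * (n - 1)
        pairs += n * (n - 1)
    return total / pairs


def degree_centralization(net: nx.Graph) -> float:
    """Freeman degree centralization Σ(k_max − k_i) / ((n−1)(n−2))."""
    n = net.number_of_nodes()
    if n < 3:
        raise ValueError(f"degree centralization needs >= 3 nodes, got {n}")
    degrees = np.array([d for _, d in net.degree()])
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def topology_report(net: nx.Graph, partition: dict | None = None, seed: int = 0) -> dict:
    """Topology summary of a network: the standard survey-table metrics."""
    if partition is None:
        partition = detect_modules(net, seed=seed)
    n_nodes = net.number_of_nodes()
    n_edges = net.number_of_edges()
    return {
        "nodes": n_nodes,
        "edges": n_edges,
        "modularity": modularity(net, partition),
        "avg_clustering_coefficient": avg_clustering(net),
        "avg_path_length": avg_path_length(net),
        "avg_degree": 2.0 * n_edges / n_nodes,
        # undefined for fewer than 3 nodes; reported as missing
        "degree_centralization": (
            degree_centralization(net) if n_nodes >= 3 else None
        ),
        "n_modules": len(set(partition.values())),
    }


def module_abundance(table: pd.DataFrame, partition: dict, ddof: int = 0) -> pd.DataFrame:
    """Per-sample module abundance: mean z-scored relative abundance of members.

    Each member ASV's relative abundance series is standardized across samples
    (population SD by default; zero-variance series become all-zero); the
    module score for a sample is the mean of its members' z-scores.
    """
    missing = [a for a in partition if a not in table.columns]
    if missing:
        raise ValueError(f"partition ASVs absent from table: {missing[:5]}")
    rel = table.div(table.sum(axis=1), axis=0)
    sub = rel[list(partition)]
    sd = sub.std(axis=0, ddof=ddof)
    z = (sub - sub.mean(axis=0)) / sd.replace(0.0, np.nan)
    z = z.fillna(0.0)
    labels = sorted(set(partition.values()))
    out = pd.DataFrame(index=table.index, columns=[f"module_{m}" for m in labels], dtype=float)
    for m in labels:
        members = [a for a, lab in partition.items() if lab == m]
        if not members:
            raise ValueError(f"module {m} has no member ASVs in the table")
        out[f"module_{m}"] = z[members].mean(axis=1)
    return out
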