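"""Genus-level co-occurrence networks and keystone taxon identification.

Edges connect genus pairs with strong (Spearman |rho| > 0.6) and significant
(FDR-adjusted P < 0.001) correlations across samples, after removing rare
genera (mean relative abundance < 0.01%).  Topology metrics follow standard
graph definitions; keystones are nodes jointly in the high-degree, high-
closeness and low-betweenness fractions of the network — the direction of
the criterion is fixed, the quantile cutoffs (80/80/50) are this package's
calibration and are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_taxa import adjust_pvalues
from .datasets import OtuTable, ValidationError, relative_abundance

__all__ = [
    "CooccurrenceNetwork",
    "NetworkTopology",
    "correlation_network",
    "network_topology",
    "node_centralities",
    "identify_keystones",
    "spearman_matrix",
]


@dataclass
class CooccurrenceNetwork:
    """Undirected signed genus graph plus the thresholds that built it."""

    graph: nx.Graph
    r_threshold: float
    p_threshold: float
    edges: pd.DataFrame  # columns: source, target, rho, adjusted_p, sign
    n_pairs_tested: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_path_length: float
    clustering_coefficient: float
    graph_density: float
    modularity: float
    fraction_negative_edges: float


def _spearman_exact_p(rho: float, x: np.ndarray, y: np.ndarray, n_perm: int, rng) -> float:
    """Permutation p-value for small n where the t-approximation is poor."""
    count = 1
    for _ in range(n_perm):
        perm_rho = stats.spearmanr(x, rng.permutation(y)).statistic
        if abs(perm_rho) >= abs(rho) - 1e-12:
            count += 1
    return count / (n_perm + 1)


def spearman_matrix(
    values: pd.DataFrame, exact_below_n: int = 10, n_perm: int = 999, seed: int = 0
):
    """All-pairs Spearman rho and two-sided p over DataFrame columns.

    Uses average ranks for ties and the t-approximation for n >=
    *exact_below_n*; below that, a seeded permutation test.
    """
    n, m = values.shape
    arr = values.to_numpy(dtype=float)
    rho, p = stats.spearmanr(arr)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    if n < exact_below_n:
        rng = np.random.default_rng(seed)
        for i in range(m):
            for j in range(i + 1, m):
                p[i, j] = p[j, i] = _spearman_exact_p(rho[i, j], arr[:, i], arr[:, j], n_perm, rng)
    return (
        pd.DataFrame(rho, index=values.columns, columns=values.columns),
        pd.DataFrame(p, index=values.columns, columns=values.columns),
    )


def correlation_network(
    table: OtuTable,
    min_mean_abund: float = 1e-4,
    r_threshold: float = 0.6,
    p_threshold: float = 0.001,
    adjust: str = "bh",
    phylum_labels: pd.Series | None = None,
    seed: int = 0,
) -> CooccurrenceNetwork:
    """Build a co-occurrence network from a genus-level count table.

    Genera with mean relative abundance below *min_mean_abund* are removed,
    all remaining pairs are tested (Spearman, two-sided), p-values are
    adjusted as one family over every tested pair, and edges keep pairs with
    |rho| > r_threshold and adjusted p < p_threshold.  Isolated nodes are
    dropped.
    """
    n_samples = table.shape[0]
    if n_samples < 10:
        raise ValidationError("correlation network needs >= 10 samples")
    if n_samples < 30:
        warnings.warn("fewer than 30 samples: correlations will be unstable", stacklevel=2)
    rel = relative_abundance(table)
    keep = rel.columns[rel.mean(axis=0) >= min_mean_abund]
    if len(keep) < 2:
        raise ValidationError("fewer than 2 genera pass the abundance filter")
    rel = rel[keep]
    rho, p = spearman_matrix(rel, seed=seed)

    iu = np.triu_indices(len(keep), k=1)
    pairs = pd.DataFrame(
        {
            "source": np.asarray(keep)[iu[0]],
            "target": np.asarray(keep)[iu[1]],
            "rho": rho.to_numpy()[iu],
            "p_value": p.to_numpy()[iu],
        }
    )
    pairs["adjusted_p"] = adjust_pvalues(np.nan_to_num(pairs["p_value"], nan=1.0), adjust)
    mask = (pairs["rho"].abs() > r_threshold) & (pairs["adjusted_p"] < p_threshold)
    edges = pairs.loc[mask].copy()
    edges["sign"] = np.where(edges["rho"] > 0, "positive", "negative")

    g = nx.Graph()
    mean_ab = rel.mean(axis=0)
    for _, row in edges.iterrows():
        g.add_edge(row["source"], row["target"], rho=float(row["rho"]),
                   adjusted_p=float(row["adjusted_p"]), sign=row["sign"])
    for node in g.nodes:
        g.nodes[node]["mean_abundance"] = float(mean_ab[node])
        if phylum_labels is not None and node in phylum_labels.index:
            g.nodes[node]["phylum"] = str(phylum_labels[node])
    # post-hoc invariant: every retained edge satisfies both thresholds
    for _, _, d in g.edges(data=True):
        assert abs(d["rho"]) > r_threshold and d["adjusted_p"] < p_threshold
    return CooccurrenceNetwork(
        graph=g,
        r_threshold=r_threshold,
        p_threshold=p_threshold,
        edges=edges.reset_index(drop=True),
        n_pairs_tested=len(pairs),
    )


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, CooccurrenceNetwork) else net


def network_topology(net, seed: int = 0) -> NetworkTopology:
    """Graph-level topology: degree, path length (largest component),
    clustering, density, greedy modularity, negative-edge fraction."""
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValidationError("empty network")
    degrees = [d for _, d in g.degree()]
    largest_cc = g.subgraph(max(nx.connected_components(g), key=len))
    apl = (
        nx.average_shortest_path_length(largest_cc)
        if largest_cc.number_of_nodes() > 1
        else 0.0
    )
    communities = nx.community.greedy_modularity_communities(g)
    modularity = nx.community.modularity(g, communities) if g.number_of_edges() else 0.0
    signs = [d.get("sign", "positive") for _, _, d in g.edges(data=True)]
    frac_neg = signs.count("negative") / len(signs) if signs else 0.0
    return NetworkTopology(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        average_degree=float(np.mean(degrees)),
        average_path_length=float(apl),
        clustering_coefficient=float(nx.average_clustering(g)),
        graph_density=float(nx.density(g)),
        modularity=float(modularity),
        fraction_negative_edges=float(frac_neg),
    )


def node_centralities(net) -> pd.DataFrame:
    """Per-node degree, normalized betweenness, and closeness centrality.

    Closeness is computed within each connected component (no cross-component
    scaling), so a clique member scores 1 regardless of other components.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValidationError("empty network")
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    rows = pd.DataFrame(
        {
            "degree": pd.Series(dict(g.degree()), dtype=float),
            "betweenness": pd.Series(betweenness),
            "closeness": pd.Series(closeness),
        }
    )
    return rows.sort_index()


def identify_keystones(
    metrics: pd.DataFrame,
    degree_q: float = 0.8,
    closeness_q: float = 0.8,
    betweenness_q: float = 0.5,
) -> list[str]:
    """Keystone = degree >= its q-quantile AND closeness >= its q-quantile
    AND betweenness <= its q-quantile (quantiles over nodes, ties inclusive)."""
    if len(metrics) < 5:
        raise ValidationError("keystone identification needs >= 5 nodes")
    # discrete quantiles land on observed values, making ties inclusive:
    # "lower" for the >= cuts, "higher" for the <= cut
    deg_cut = np.quantile(metrics["degree"], degree_q, method="lower")
    clo_cut = np.quantile(metrics["closeness"], closeness_q, method="lower")
    bet_cut = np.quantile(metrics["betweenness"], betweenness_q, method="higher")
    mask = (
        (metrics["degree"] >= deg_cut)
        & (metrics["closeness"] >= clo_cut)
        & (metrics["betweenness"] <= bet_cut)
    )
    return sorted(metrics.index[mask])
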