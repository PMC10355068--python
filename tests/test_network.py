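import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gmeb.datasets import OtuTable, ValidationError
from gmeb.network import (
    correlation_network,
    identify_keystones,
    network_topology,
    node_centralities,
    spearman_matrix,
)


def _table(values: np.ndarray, prefix="g"):
    n, m = values.shape
    return OtuTable(values.astype(int), [f"s{i}" for i in range(n)],
                    [f"{prefix}{j}" for j in range(m)])


class TestCorrelationNetwork:
    def test_perfect_positive_and_negative_edges(self):
        base = np.arange(1, 13)
        counts = np.column_stack([base, base * 2, base[::-1], np.full(12, 500)])
        net = correlation_network(_table(counts), min_mean_abund=0.0)
        e = net.edges.set_index(["source", "target"])
        assert e.loc[("g0", "g1"), "sign"] == "positive"
        assert e.loc[("g0", "g1"), "rho"] == pytest.approx(1.0)
        assert e.loc[("g0", "g2"), "sign"] == "negative"
        assert e.loc[("g0", "g2"), "rho"] == pytest.approx(-1.0)

    def test_independent_noise_produces_no_edges(self):
        rng = np.random.default_rng(15)
        counts = rng.integers(1, 100, size=(50, 20))
        net = correlation_network(_table(counts), min_mean_abund=0.0)
        assert net.n_edges == 0

    def test_edges_satisfy_both_thresholds(self):
        rng = np.random.default_rng(4)
        shared = rng.normal(size=30)
        counts = np.column_stack([
            (np.exp(shared + rng.normal(0, 0.2, 30)) * 50 + 1).astype(int)
            for _ in range(6)] + [rng.integers(1, 80, (30, 6)).T.reshape(30, -1)[:, i]
                                  for i in range(6)])
        net = correlation_network(_table(counts), min_mean_abund=0.0)
        assert (net.edges["rho"].abs() > net.r_threshold).all()
        assert (net.edges["adjusted_p"] < net.p_threshold).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            correlation_network(_table(np.ones((5, 4), int)))

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(40, 6)))
        df.columns = [f"c{i}" for i in range(6)]
        rho, _ = spearman_matrix(df)
        ranks = df.rank()
        for i in range(6):
            for j in range(i + 1, 6):
                expect = stats.pearsonr(ranks.iloc[:, i], ranks.iloc[:, j])[0]
                assert rho.iloc[i, j] == pytest.approx(expect, abs=1e-12)


class TestTopology:
    def test_complete_graph(self):
        topo = network_topology(nx.complete_graph(4))
        assert topo.average_degree == 3
        assert topo.graph_density == 1
        assert topo.clustering_coefficient == 1
        assert topo.average_path_length == 1

    def test_path_graph_hand_values(self):
        topo = network_topology(nx.path_graph(3))
        assert topo.graph_density == pytest.approx(2 / 3)
        assert topo.average_path_length == pytest.approx(4 / 3)

    def test_adding_edge_never_decreases_density(self):
        g = nx.path_graph(6)
        before = network_topology(g).graph_density
        g.add_edge(0, 5)
        assert network_topology(g).graph_density > before

    def test_empty_network_errors(self):
        with pytest.raises(ValidationError):
            network_topology(nx.Graph())


class TestCentralities:
    def test_star_center(self):
        m = node_centralities(nx.star_graph(4))  # center 0, leaves 1..4
        assert m.loc[0, "degree"] == 4
        # raw betweenness 6 (all leaf pairs) / ((n-1)(n-2)/2) = 1 normalized
        assert m.loc[0, "betweenness"] == pytest.approx(1.0)
        assert m.loc[1, "closeness"] < m.loc[0, "closeness"]

    def test_complete_graph_betweenness_zero(self):
        m = node_centralities(nx.complete_graph(4))
        assert (m["betweenness"] == 0).all()


class TestKeystones:
    def test_clique_with_chain(self):
        """5-clique with a 3-node chain hanging off one member: interior
        clique members are keystones, the articulation node is not."""
        g = nx.complete_graph(5)
        nx.add_path(g, [4, 5, 6, 7])
        ks = identify_keystones(node_centralities(g))
        assert set(ks) <= {0, 1, 2, 3}
        assert len(ks) == 4
        assert 4 not in ks  # articulation node: maximal betweenness

    def test_all_tied_nodes_all_flagged(self):
        ks = identify_keystones(node_centralities(nx.complete_graph(5)))
        assert len(ks) == 5

    def test_star_center_excluded(self):
        ks = identify_keystones(node_centralities(nx.star_graph(5)))
        assert 0 not in ks

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValidationError):
            identify_keystones(node_centralities(nx.complete_graph(4)))


def make_planted_two_block(n=200, rho=0.9, n_block=9, n_noise=6, seed=0):
    """Genus table with two correlated blocks joined by one articulation
    genus, plus independent noise genera.  Returns (table, planted_edges)."""
    rng = np.random.default_rng(seed)
    fa, fb = rng.normal(size=n), rng.normal(size=n)
    lam = np.sqrt(rho)
    cols, names = [], []
    for b, f in (("A", fa), ("B", fb)):
        for i in range(n_block):
            cols.append(lam * f + np.sqrt(1 - rho) * rng.normal(size=n))
            names.append(f"{b}{i}")
    cols.append((fa + fb) / np.sqrt(2))
    names.append("ART")
    for i in range(n_noise):
        cols.append(rng.normal(size=n))
        names.append(f"N{i}")
    # bounded rank-preserving transform keeps the Spearman structure; a
    # filler genus pins every row total to the same constant so that
    # closing the composition does not distort the designed correlations
    base = (1000 * stats.norm.cdf(np.column_stack(cols))).astype(int) + 1
    fill = base.sum(axis=1).max() + 5000 - base.sum(axis=1)
    counts = np.column_stack([base, fill])
    names.append("FILL")
    table = OtuTable(counts, [f"s{i}" for i in range(n)], names)
    planted = set()
    for b in ("A", "B"):
        members = [f"{b}{i}" for i in range(n_block)]
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                planted.add(frozenset((u, v)))
            planted.add(frozenset((u, "ART")))
    return table, planted


def evaluate_planted_recovery(seed=2, n=200, rho=0.9):
    """Build the planted table, run the network pipeline, and score edge
    recovery (the constant-total filler is scaffolding, not structure)."""
    table, planted = make_planted_two_block(n=n, rho=rho, seed=seed)
    net = correlation_network(table, min_mean_abund=0.0)
    g = net.graph
    if "FILL" in g:
        g.remove_node("FILL")
    found = {frozenset((r.source, r.target)) for r in net.edges.itertuples()
             if "FILL" not in (r.source, r.target)}
    tp = len(found & planted)
    ks = identify_keystones(node_centralities(g))
    return tp / len(found), tp / len(planted), ks


def test_planted_block_recovery_precision_recall():
    precision, recall, ks = evaluate_planted_recovery(seed=2)
    assert precision >= 0.9 and recall >= 0.9
    assert "ART" not in ks
    assert any(k[0] in "AB" for k in ks)
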