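import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phagenet import (
    CooccurrenceNetwork,
    CorrelationScreen,
    spearman_screen,
    bh_fdr,
    build_network,
    topology,
    keystone_zscore,
    modularity_partition,
    modularity_q,
    network_summary,
    summary_from_counts,
    compare_node_attributes,
)
from conftest import make_table


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_topology(g: nx.Graph):
    """All four node metrics recomputed from scratch (BFS + path-count DP)."""
    nodes = sorted(g)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    INF = float("inf")
    dist = np.full((n, n), INF)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = idx[s]
        dist[si, si] = 0
        sigma[si, si] = 1
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for u in frontier:
                for v in g[u]:
                    if dist[si, idx[v]] == INF:
                        dist[si, idx[v]] = d + 1
                        nxt.append(v)
            for u in set(nxt):
                sigma[si, idx[u]] = sum(
                    sigma[si, idx[w]] for w in g[u] if dist[si, idx[w]] == d
                )
            frontier = nxt
            d += 1
    betweenness = {}
    for v in nodes:
        vi = idx[v]
        total = 0.0
        for s, t in itertools.combinations(nodes, 2):
            si, ti = idx[s], idx[t]
            if v in (s, t) or dist[si, ti] == INF:
                continue
            if dist[si, vi] + dist[vi, ti] == dist[si, ti]:
                total += sigma[si, vi] * sigma[vi, ti] / sigma[si, ti]
        betweenness[v] = total
    closeness = {}
    for v in nodes:
        vi = idx[v]
        reach = [dist[vi, j] for j in range(n) if j != vi and dist[vi, j] < INF]
        if not reach:
            closeness[v] = 0.0
        else:
            r = len(reach)
            closeness[v] = (r / (n - 1)) * (r / sum(reach))
    comps = list(nx.connected_components(g))
    lcc = sorted(max(comps, key=lambda c: (len(c), sorted(c))))
    A = np.zeros((len(lcc), len(lcc)))
    pos = {v: i for i, v in enumerate(lcc)}
    for u, v in g.edges():
        if u in pos and v in pos:
            A[pos[u], pos[v]] = A[pos[v], pos[u]] = 1
    eigen = {v: 0.0 for v in nodes}
    if A.any():
        w, V = np.linalg.eigh(A)
        vec = np.abs(V[:, np.argmax(w)])
        vec /= vec.max()
        eigen.update({v: vec[pos[v]] for v in lcc})
    degree = dict(g.degree())
    return degree, betweenness, closeness, eigen


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield [[first]] + part


def best_partition_q(g: nx.Graph) -> float:
    best = -1.0
    for part in set_partitions(sorted(g)):
        assignment = {v: i for i, block in enumerate(part) for v in block}
        best = max(best, modularity_q(g, assignment))
    return best


def bh_oracle(p):
    """Textbook step-up: q_(i) = min over j>=i of p_(j)·m/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def net_from_edges(edges, domains=None) -> CooccurrenceNetwork:
    g = nx.Graph()
    nodes = sorted({v for e in edges for v in e})
    domains = domains or {}
    for v in nodes:
        g.add_node(v, domain=domains.get(v, "bacteria"), family="FamX")
    for u, v in edges:
        g.add_edge(u, v, rho=0.9, q=0.001, sign="+")
    return CooccurrenceNetwork(g, "bacteria" if not domains else "interdomain")


# ---------------------------------------------------------------------------
# Spearman screen
# ---------------------------------------------------------------------------


class TestSpearmanScreen:
    def test_monotone_and_antimonotone_pairs(self):
        values = np.array(
            [[1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [10, 8, 6, 4, 2.0]], dtype=float
        )
        screen = spearman_screen(make_table(values))
        pairs = screen.pairs.set_index(["taxon_a", "taxon_b"])
        assert pairs.loc[("T00", "T01"), "rho"] == pytest.approx(1.0)
        assert pairs.loc[("T00", "T02"), "rho"] == pytest.approx(-1.0)

    def test_tied_toy_matches_midrank_oracle(self):
        values = np.array([[1, 2, 2, 3, 4], [4, 4, 2, 1, 1.0]])
        screen = spearman_screen(make_table(values))
        expected = stats.spearmanr(values[0], values[1]).statistic
        assert screen.pairs["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_exact_small_n_p_for_perfect_monotone(self):
        # n = 5, tie-free: P(|rho| = 1) = 2/5! = 1/60
        values = np.array([[1, 2, 3, 4, 5], [3, 5, 7, 11, 13.0]])
        screen = spearman_screen(make_table(values))
        assert screen.pairs["p_raw"].iloc[0] == pytest.approx(1.0 / 60.0)

    def test_constant_taxa_excluded(self):
        values = np.array([[1, 2, 3, 4, 5], [2, 2, 2, 2, 2.0], [5, 3, 4, 1, 2.0]])
        screen = spearman_screen(make_table(values))
        assert screen.dropped_constant == ["T01"]
        assert screen.n_tests == 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            spearman_screen(make_table(np.ones((3, 3))))

    def test_cross_mode_only_interdomain_pairs(self, toy_table):
        screen = spearman_screen(toy_table, mode="cross")
        doms = toy_table.taxonomy["domain"]
        for row in screen.pairs.itertuples():
            assert doms[row.taxon_a] != doms[row.taxon_b]


class TestBhFdr:
    def test_closed_form_equal_spacing(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_random_vector_matches_step_up_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.random(57)
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(40)
        assert (bh_fdr(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def screen_from_rows(rows):
    taxa = sorted({r[0] for r in rows} | {r[1] for r in rows})
    taxonomy = pd.DataFrame(
        {"domain": "bacteria", "phylum": "P", "order": "O", "family": "F"},
        index=pd.Index(taxa, name="taxon_id"),
    )
    pairs = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p_raw", "q"])
    return CorrelationScreen(pairs, len(pairs), "bacteria", None, taxonomy, 20)


class TestBuildNetwork:
    def test_all_insignificant_yields_empty_network(self):
        net = build_network(screen_from_rows([("a", "b", 0.9, 1.0, 1.0)]))
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_single_passing_pair(self):
        net = build_network(screen_from_rows([("a", "b", 0.9, 1e-4, 0.001)]))
        assert net.n_nodes == 2 and net.n_edges == 1
        assert net.graph.edges["a", "b"]["sign"] == "+"

    def test_thresholds_are_inclusive(self):
        net = build_network(screen_from_rows([("a", "b", 0.6, 0.001, 0.01)]))
        assert net.n_edges == 1

    def test_just_below_thresholds_excluded(self):
        rows = [("a", "b", 0.59, 0.001, 0.001), ("c", "d", 0.9, 0.001, 0.011)]
        assert build_network(screen_from_rows(rows)).n_edges == 0

    def test_isolated_taxa_not_counted_as_nodes(self):
        rows = [("a", "b", 0.9, 1e-4, 1e-3), ("c", "d", 0.1, 0.9, 0.95)]
        net = build_network(screen_from_rows(rows))
        assert set(net.graph) == {"a", "b"}

    def test_rescreen_of_small_table_reproduces_edge_set(self):
        """Thresholding exactness against a from-scratch re-screen."""
        rng = np.random.default_rng(12)
        base = rng.normal(size=12)
        values = np.exp(
            [base + rng.normal(scale=s, size=12) for s in (0.1, 0.2, 0.5, 3.0, 3.0)]
        )
        table = make_table(values)
        net = build_network(spearman_screen(table), rho_min=0.6, q_max=0.05)
        # oracle: scipy spearman matrix + textbook BH + inclusive thresholds
        rho, p = stats.spearmanr(values, axis=1)
        iu = np.triu_indices(5, 1)
        q = bh_oracle(p[iu])
        expected = {
            (f"T{i:02d}", f"T{j:02d}")
            for (i, j), rr, qq in zip(zip(*iu), rho[iu], q)
            if abs(rr) >= 0.6 and qq <= 0.05
        }
        assert set(map(tuple, map(sorted, net.graph.edges()))) == expected


# ---------------------------------------------------------------------------
# topology / keystones / modularity / summary
# ---------------------------------------------------------------------------


class TestTopology:
    def test_star_closed_forms(self):
        net = net_from_edges([("hub", f"leaf{i}") for i in range(5)])
        topo = topology(net)
        assert topo.loc["hub", "degree"] == 5
        assert topo.loc["hub", "betweenness"] == pytest.approx(10.0)  # C(5,2) leaf pairs
        assert (topo.drop("hub")["degree"] == 1).all()
        assert topo.loc["hub", "closeness"] == pytest.approx(1.0)
        assert topo.loc["hub", "eigenvector"] == pytest.approx(1.0)

    def test_cycle_symmetry(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        topo = topology(net)
        assert (topo["degree"] == 2).all()
        assert topo["betweenness"].nunique() == 1
        assert topo["eigenvector"].min() == pytest.approx(1.0)

    def test_seven_node_toy_matches_brute_force(self):
        edges = [
            ("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"),
            ("d", "e"), ("e", "f"), ("f", "d"), ("g", "a"),
        ]
        net = net_from_edges(edges)
        topo = topology(net)
        deg, btw, clo, eig = brute_force_topology(net.graph)
        for v in topo.index:
            assert topo.loc[v, "degree"] == deg[v]
            assert topo.loc[v, "betweenness"] == pytest.approx(btw[v], abs=1e-9)
            assert topo.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-9)
            assert topo.loc[v, "eigenvector"] == pytest.approx(eig[v], abs=1e-6)

    def test_disconnected_components_handled(self):
        net = net_from_edges([("a", "b"), ("c", "d"), ("d", "e"), ("e", "c")])
        topo = topology(net)
        deg, btw, clo, eig = brute_force_topology(net.graph)
        for v in topo.index:
            assert topo.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-9)
            assert topo.loc[v, "eigenvector"] == pytest.approx(eig[v], abs=1e-6)

    def test_empty_network_rejected(self):
        net = CooccurrenceNetwork(nx.Graph(), "bacteria")
        with pytest.raises(ValueError):
            topology(net)


class TestKeystones:
    def test_star_center_ranks_first(self):
        topo = topology(net_from_edges([("hub", f"leaf{i}") for i in range(6)]))
        ranked = keystone_zscore(topo, top_n=3)
        assert ranked.index[0] == "hub"
        assert ranked["z_score"].iloc[0] > 0

    def test_regular_graph_all_zero_scores_tie_broken_by_id(self):
        topo = topology(net_from_edges([("a", "b"), ("b", "c"), ("c", "a")]))
        ranked = keystone_zscore(topo, top_n=2)
        assert (ranked["z_score"] == 0).all()
        assert ranked.index.tolist() == ["a", "b"]

    def test_small_network_returns_all_nodes(self):
        topo = topology(net_from_edges([("a", "b")]))
        assert len(keystone_zscore(topo, top_n=10)) == 2


class TestModularity:
    def test_two_triangles_reach_exhaustive_optimum_half(self):
        g = net_from_edges(
            [("a", "b"), ("b", "c"), ("c", "a"), ("x", "y"), ("y", "z"), ("z", "x")]
        )
        part = modularity_partition(g)
        assert part.modularity_Q == pytest.approx(0.5, abs=1e-12)
        assert best_partition_q(g.graph) == pytest.approx(0.5, abs=1e-12)
        comps = {frozenset(v for v, m in part.assignment.items() if m == mod)
                 for mod in set(part.assignment.values())}
        assert comps == {frozenset("abc"), frozenset("xyz")}

    def test_complete_graph_trivial_partition_q_zero(self):
        g = net_from_edges(list(itertools.combinations("abcd", 2)))
        assert modularity_q(g.graph, {v: 0 for v in g.graph}) == pytest.approx(0.0)

    def test_eight_node_toy_within_002_of_exhaustive_optimum(self):
        edges = [
            ("a", "b"), ("b", "c"), ("c", "a"), ("c", "d"), ("d", "e"),
            ("e", "f"), ("f", "d"), ("f", "g"), ("g", "h"), ("h", "e"),
        ]
        net = net_from_edges(edges)
        part = modularity_partition(net)
        assert part.modularity_Q >= best_partition_q(net.graph) - 0.02

    def test_partition_q_self_consistent_to_1e12(self, toy_table):
        rng = np.random.default_rng(2)
        base = rng.normal(size=16)
        values = np.exp([base + rng.normal(scale=s, size=16)
                         for s in (0.1, 0.15, 0.2, 4.0, 4.0, 4.0)])
        net = build_network(spearman_screen(make_table(values)), rho_min=0.5, q_max=0.2)
        part = modularity_partition(net)
        from phagenet.network import _canonical

        assert modularity_q(_canonical(net.graph), part.assignment) == pytest.approx(
            part.modularity_Q, abs=1e-12
        )

    def test_edgeless_network_rejected(self):
        net = CooccurrenceNetwork(nx.Graph(), "bacteria")
        with pytest.raises(ValueError):
            modularity_partition(net)


class TestSummary:
    def test_counts_and_rates_from_network(self):
        g = nx.Graph()
        for v in "abcd":
            g.add_node(v, domain="bacteria", family="F")
        g.add_edge("a", "b", rho=0.9, q=1e-3, sign="+")
        g.add_edge("b", "c", rho=0.8, q=1e-3, sign="+")
        g.add_edge("c", "d", rho=-0.7, q=1e-3, sign="-")
        net = CooccurrenceNetwork(g, "bacteria")
        s = network_summary(net)
        assert (s.node_count, s.edge_count) == (4, 3)
        assert (s.positive_edges, s.negative_edges) == (2, 1)
        assert s.positive_rate == pytest.approx(66.67)
        assert s.negative_rate == pytest.approx(33.33)
        assert s.average_degree == pytest.approx(1.5)

    def test_rates_always_sum_to_100(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            pos = int(rng.integers(0, 500))
            neg = int(rng.integers(0, 500))
            if pos + neg == 0:
                continue
            s = summary_from_counts(10, pos + neg, pos, neg)
            assert s.positive_rate + s.negative_rate == pytest.approx(100.0, abs=0.011)

    def test_empty_network_summary_blank(self):
        s = network_summary(CooccurrenceNetwork(nx.Graph(), "bacteria"))
        assert s.edge_count == 0 and s.positive_rate is None

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            summary_from_counts(10, 5, 2, 2)


class TestCompareNodeAttributes:
    def test_identical_distributions_high_p(self):
        net = net_from_edges(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")],
            domains={"a": "bacteria", "b": "phage", "c": "bacteria", "d": "phage"},
        )
        topo = topology(net)
        res = compare_node_attributes(
            topo, {v: net.graph.nodes[v]["domain"] for v in topo.index}
        )
        assert (res["p"] > 0.9).all()

    def test_separated_degrees_extreme_u_minimal_p(self):
        # K4 (all degree 3) disjoint from a 4-path (degrees 1,2,2,1):
        # the two classes have completely separated degree distributions
        edges = list(itertools.combinations("abcd", 2)) + [
            ("p", "q"), ("q", "r"), ("r", "s")
        ]
        topo = topology(net_from_edges(edges))
        grouping = {v: ("clique" if v in "abcd" else "path") for v in topo.index}
        res = compare_node_attributes(topo, grouping).set_index("attribute")
        U = res.loc["degree", "U"]
        assert min(U, 16 - U) == 0.0
        # minimal attainable two-sided exact p at n = m = 4
        assert res.loc["degree", "p"] == pytest.approx(2 / 70)

    def test_single_class_rejected(self):
        topo = topology(net_from_edges([("a", "b")]))
        with pytest.raises(ValueError):
            compare_node_attributes(topo, {"a": "x", "b": "x"})
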