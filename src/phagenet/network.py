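"""Co-occurrence networks: Spearman screen, FDR, topology, keystones, modularity.

A network is built per (group, mode): Spearman rank correlations over all
taxon pairs of the requested mode ('bacteria', 'phage', 'interdomain' — both
domains with all passing edges — or 'cross', restricted to bacteria–phage
pairs), Benjamini–Hochberg correction over that family of tests, then an edge
for every pair with |ρ| ≥ rho_min and q ≤ q_max (inclusive thresholds).
Isolated taxa are dropped, so node counts refer to connected taxa.

Topology metrics are unweighted and sign-blind: degree; betweenness as raw
shortest-path pair counts; closeness with the Wasserman–Faust component-aware
scaling (in [0, 1]); eigenvector centrality by power iteration on the largest
connected component (rescaled to max 1, zero elsewhere). The keystone score of
a node is the sum of its standardized degree and standardized closeness —
standardizing puts the integer degree and the [0,1] closeness on a common
scale so both contribute — and the top 10 scores per network mark the
keystone taxa. Module structure comes from Newman's fast-greedy modularity
agglomeration, which is deterministic once the node order is canonicalized.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable
from .diversity import mann_whitney

logger = logging.getLogger(__name__)

MODES = ("bacteria", "phage", "interdomain", "cross", "all")


@dataclass
class CorrelationScreen:
    """All tested taxon pairs with Spearman ρ, raw p, and BH-adjusted q."""

    pairs: pd.DataFrame  # columns: taxon_a, taxon_b, rho, p_raw, q
    n_tests: int
    mode: str
    group: str | None
    taxonomy: pd.DataFrame
    n_samples: int
    dropped_constant: list[str] = field(default_factory=list)


@dataclass
class CooccurrenceNetwork:
    """Undirected signed graph over taxa; every edge carries (rho, q, sign)."""

    graph: nx.Graph
    mode: str
    group: str | None = None
    rho_min: float = 0.6
    q_max: float = 0.01

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError("self-loop in network")
            if abs(d["rho"]) < self.rho_min - 1e-12 or d["q"] > self.q_max + 1e-12:
                raise ValueError(f"edge ({u}, {v}) violates the admission thresholds")
        if self.mode in ("bacteria", "phage"):
            bad = [n for n, d in self.graph.nodes(data=True) if d.get("domain") != self.mode]
            if bad:
                raise ValueError(f"{self.mode} network contains foreign nodes: {bad}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": u, "taxon_b": v, "rho": d["rho"], "q": d["q"], "sign": d["sign"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "q", "sign"])


@dataclass
class ModulePartition:
    assignment: dict[str, int]
    modularity_Q: float

    def __post_init__(self) -> None:
        if not -0.5 - 1e-9 <= self.modularity_Q <= 1.0 + 1e-9:
            raise ValueError(f"modularity {self.modularity_Q} outside [-0.5, 1]")


@dataclass
class NetworkSummary:
    """One row of the per-network topology summary table."""

    node_count: int
    edge_count: int
    positive_edges: int
    negative_edges: int
    positive_rate: float | None
    negative_rate: float | None
    average_degree: float | None
    modularity_Q: float | None

    def __post_init__(self) -> None:
        if self.positive_edges + self.negative_edges != self.edge_count:
            raise ValueError("positive + negative edges must equal the edge count")
        if self.edge_count > 0:
            total = round(self.positive_rate + self.negative_rate, 6)
            if abs(total - 100.0) > 0.011:  # two rates each rounded to 2 decimals
                raise ValueError("positive and negative rates must sum to 100%")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (table formatting)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Spearman screen
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _exact_spearman_null(n: int) -> np.ndarray:
    """Sorted null |ρ| values over all rank permutations (tie-free, n ≤ 9)."""
    base = np.arange(n, dtype=float)
    perms = np.array(list(itertools.permutations(range(n))), dtype=float)
    mean = (n - 1) / 2.0
    denom = ((base - mean) ** 2).sum()
    rhos = ((perms - mean) * (base - mean)).sum(axis=1) / denom
    return np.sort(np.abs(rhos))


def _exact_spearman_p(rho: float, n: int) -> float:
    null = _exact_spearman_null(n)
    k = null.size - np.searchsorted(null, abs(rho) - 1e-12, side="left")
    return k / null.size


def spearman_screen(
    table: AbundanceTable, mode: str = "all", group: str | None = None
) -> CorrelationScreen:
    """Spearman ρ (midrank ties) with two-sided p for every pair of the mode.

    p-values use the t approximation, except tie-free pairs at n ≤ 9 samples,
    which use the exact permutation null. Constant-abundance taxa have no
    defined rank correlation and are excluded (their count is logged).
    BH-FDR q-values are computed over all pairs tested within this screen.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    n = table.n_samples
    if n < 4:
        raise ValueError("Spearman screen needs at least 4 samples")
    if table.n_taxa < 2:
        raise ValueError("Spearman screen needs at least 2 taxa")

    if mode == "bacteria":
        sub = table.subset_domain("bacteria")
    elif mode == "phage":
        sub = table.subset_domain("phage")
    else:
        sub = table

    X = sub.values.to_numpy(dtype=float)
    constant = np.ptp(X, axis=1) == 0
    dropped = [t for t, c in zip(sub.taxon_ids, constant) if c]
    if dropped:
        logger.warning("excluding %d constant-abundance taxa from the screen", len(dropped))
    taxa = [t for t, c in zip(sub.taxon_ids, constant) if not c]
    X = X[~constant]
    domains = sub.taxonomy.loc[taxa, "domain"].to_numpy()

    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    R = np.corrcoef(ranks)
    has_ties = np.array([np.unique(row).size < n for row in ranks])

    if mode == "cross":
        pair_idx = [
            (i, j)
            for i, j in itertools.combinations(range(len(taxa)), 2)
            if domains[i] != domains[j]
        ]
    else:
        pair_idx = list(itertools.combinations(range(len(taxa)), 2))

    rows = []
    for i, j in pair_idx:
        rho = float(np.clip(R[i, j], -1.0, 1.0))
        if n <= 9 and not (has_ties[i] or has_ties[j]):
            p = _exact_spearman_p(rho, n)
        else:
            if abs(rho) >= 1.0:
                p = 0.0
            else:
                t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
                p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        rows.append((taxa[i], taxa[j], rho, float(p)))

    pairs = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p_raw"])
    pairs["q"] = bh_fdr(pairs["p_raw"].to_numpy()) if len(pairs) else np.array([])
    return CorrelationScreen(
        pairs, len(pairs), mode, group, sub.taxonomy.loc[taxa], n, dropped
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def build_network(
    screen: CorrelationScreen,
    rho_min: float = 0.6,
    q_max: float = 0.01,
    mode: str | None = None,
) -> CooccurrenceNetwork:
    """Admit exactly the pairs with |ρ| ≥ rho_min and q ≤ q_max (inclusive).

    Taxa with no passing edge are not nodes: node counts refer to connected
    taxa. An empty screen or no passing pair yields an empty network (warning).
    """
    if not 0 < rho_min <= 1:
        raise ValueError("rho_min must be in (0, 1]")
    if not 0 < q_max <= 1:
        raise ValueError("q_max must be in (0, 1]")
    mode = mode or screen.mode
    g = nx.Graph()
    passing = screen.pairs[
        (screen.pairs["rho"].abs() >= rho_min - 1e-12)
        & (screen.pairs["q"] <= q_max + 1e-12)
    ]
    if passing.empty:
        logger.warning("no pair passes |rho| >= %.2f and q <= %.3g", rho_min, q_max)
    tax = screen.taxonomy
    for row in passing.itertuples(index=False):
        for t in (row.taxon_a, row.taxon_b):
            if t not in g:
                g.add_node(
                    t,
                    domain=str(tax.loc[t, "domain"]),
                    family=str(tax.loc[t, "family"]),
                )
        g.add_edge(
            row.taxon_a,
            row.taxon_b,
            rho=float(row.rho),
            q=float(row.q),
            sign="+" if row.rho > 0 else "-",
        )
    return CooccurrenceNetwork(g, mode, screen.group, rho_min, q_max)


# ---------------------------------------------------------------------------
# topology and keystones
# ---------------------------------------------------------------------------


def _canonical(graph: nx.Graph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(sorted(graph.nodes(data=True)))
    g.add_edges_from(sorted((min(u, v), max(u, v), d) for u, v, d in graph.edges(data=True)))
    return g


def topology(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness, eigenvector, and keystone z-score.

    Betweenness is the raw (unnormalized) count of shortest-path pairs through
    the node; closeness uses the Wasserman–Faust component-aware scaling;
    eigenvector centrality is computed on the largest connected component
    (power iteration, tol 1e-10) and rescaled so its maximum is 1, with nodes
    outside that component at 0.
    """
    if net.n_nodes == 0:
        raise ValueError("topology of an empty network is undefined")
    g = _canonical(net.graph)
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False)
    closeness = nx.closeness_centrality(g, wf_improved=True)
    eigen = {node: 0.0 for node in g}
    lcc = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    sub = g.subgraph(lcc)
    if sub.number_of_edges() > 0:
        ev = nx.eigenvector_centrality(sub, max_iter=10_000, tol=1e-10)
        top = max(ev.values())
        eigen.update({node: val / top for node, val in ev.items()})
    frame = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "betweenness": pd.Series(betweenness),
            "closeness": pd.Series(closeness),
            "eigenvector": pd.Series(eigen),
        }
    ).sort_index()
    frame["z_score"] = _standardize(frame["degree"]) + _standardize(frame["closeness"])
    frame.index.name = "taxon_id"
    return frame


def _standardize(x: pd.Series) -> pd.Series:
    sd = float(x.std(ddof=0))
    if sd == 0:
        return pd.Series(0.0, index=x.index)
    return (x - x.mean()) / sd


def keystone_zscore(topo: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Rank nodes by keystone z-score (standardized degree + closeness).

    Ties break by degree, then taxon id; all nodes return when the network
    has at most ``top_n`` nodes.
    """
    if topo.empty:
        raise ValueError("topology table is empty")
    z = _standardize(topo["degree"]) + _standardize(topo["closeness"])
    ranked = topo.assign(z_score=z).reset_index()
    ranked = ranked.sort_values(
        ["z_score", "degree", "taxon_id"], ascending=[False, False, True]
    ).set_index("taxon_id")
    return ranked.head(top_n)


# ---------------------------------------------------------------------------
# modules and summaries
# ---------------------------------------------------------------------------


def modularity_partition(net: CooccurrenceNetwork) -> ModulePartition:
    """Newman fast-greedy modularity partition (unweighted, sign-blind).

    The returned Q is recomputed from the returned assignment via the standard
    Q = Σᵢ(eᵢᵢ − aᵢ²) formula and asserted self-consistent.
    """
    if net.n_edges == 0:
        raise ValueError("modularity of an edgeless network is undefined")
    g = _canonical(net.graph)
    communities = nx.algorithms.community.greedy_modularity_communities(g, weight=None)
    assignment = {
        node: idx for idx, comm in enumerate(communities) for node in sorted(comm)
    }
    q = modularity_q(g, assignment)
    q_nx = nx.algorithms.community.modularity(g, communities, weight=None)
    assert abs(q - q_nx) < 1e-12, "partition Q self-consistency violated"
    return ModulePartition(assignment, q)


def modularity_q(graph: nx.Graph, assignment: dict) -> float:
    """Q = Σᵢ(eᵢᵢ − aᵢ²): within-module edge fraction minus its degree-model expectation."""
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("Q undefined without edges")
    modules = set(assignment.values())
    e = {c: 0.0 for c in modules}
    a = {c: 0.0 for c in modules}
    for u, v in graph.edges():
        if assignment[u] == assignment[v]:
            e[assignment[u]] += 1.0 / m
    for node, deg in graph.degree():
        a[assignment[node]] += deg / (2.0 * m)
    return float(sum(e[c] - a[c] ** 2 for c in modules))


def network_summary(
    net: CooccurrenceNetwork, partition: ModulePartition | None = None
) -> NetworkSummary:
    """Node/edge counts, signed-edge rates (% to 2 decimals), 2E/N, modularity."""
    pos = sum(1 for _, _, d in net.graph.edges(data=True) if d["sign"] == "+")
    neg = net.n_edges - pos
    if net.n_edges == 0:
        return NetworkSummary(net.n_nodes, 0, 0, 0, None, None, None, None)
    return NetworkSummary(
        node_count=net.n_nodes,
        edge_count=net.n_edges,
        positive_edges=pos,
        negative_edges=neg,
        positive_rate=round_half_up(100.0 * pos / net.n_edges),
        negative_rate=round_half_up(100.0 * neg / net.n_edges),
        average_degree=round_half_up(2.0 * net.n_edges / net.n_nodes),
        modularity_Q=None if partition is None else partition.modularity_Q,
    )


def summary_from_counts(
    node_count: int,
    edge_count: int,
    positive_edges: int,
    negative_edges: int,
    modularity_Q: float | None = None,
) -> NetworkSummary:
    """Summary row from already-tabulated counts (rates and 2E/N recomputed)."""
    if edge_count == 0:
        return NetworkSummary(node_count, 0, positive_edges, negative_edges,
                              None, None, None, modularity_Q)
    return NetworkSummary(
        node_count=node_count,
        edge_count=edge_count,
        positive_edges=positive_edges,
        negative_edges=negative_edges,
        positive_rate=round_half_up(100.0 * positive_edges / edge_count),
        negative_rate=round_half_up(100.0 * negative_edges / edge_count),
        average_degree=round_half_up(2.0 * edge_count / node_count) if node_count else None,
        modularity_Q=modularity_Q,
    )


def compare_node_attributes(topo: pd.DataFrame, grouping) -> pd.DataFrame:
    """Two-sided Mann–Whitney per topology attribute between two node classes."""
    classes = pd.Series(grouping).loc[topo.index]
    levels = classes.drop_duplicates().tolist()
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 node classes, got {levels}")
    a, b = (topo.loc[classes == lv] for lv in levels)
    rows = []
    for attr in ("degree", "betweenness", "closeness", "eigenvector"):
        U, p = mann_whitney(a[attr].to_numpy(), b[attr].to_numpy())
        rows.append({"attribute": attr, "U": U, "p": p})
    return pd.DataFrame(rows)
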