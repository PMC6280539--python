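"""Tripartite network construction, triplet enumeration, and topology.

The network has three node classes (gene, miRNA, drug); edges join a gene
to a miRNA or a gene to a drug, never two nodes of the same class and
never a miRNA to a drug. The drug-pathway view built by the enrichment
stage reuses the same container with an extended set of allowed class
pairs.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .datatypes import MGDT, InteractionCatalog

__all__ = [
    "TripartiteNetwork",
    "TRIPARTITE_PAIRS",
    "DRUG_PATHWAY_PAIRS",
    "build_tripartite_network",
    "enumerate_mgdts",
    "DegreeStats",
    "degree_stats",
    "PowerLawFit",
    "fit_power_law",
    "topological_coefficients",
]

#: class pairs an edge may join in the core miRNA-gene-drug network
TRIPARTITE_PAIRS = frozenset({
    frozenset({"gene", "miRNA"}),
    frozenset({"gene", "drug"}),
})

#: extended pairs for the miRNA-mediated drug-pathway network
DRUG_PATHWAY_PAIRS = frozenset({
    frozenset({"gene", "miRNA"}),
    frozenset({"gene", "drug"}),
    frozenset({"miRNA", "pathway"}),
})


class TripartiteNetwork:
    """Typed undirected graph over gene/miRNA/drug (optionally pathway) nodes.

    A thin wrapper around :class:`networkx.Graph` that enforces the class
    constraint on every edge insertion. No self-loops; isolated nodes only
    via explicit :meth:`add_node`.
    """

    def __init__(self, allowed_pairs: frozenset = TRIPARTITE_PAIRS) -> None:
        self.graph = nx.Graph()
        self.allowed_pairs = allowed_pairs

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: str, node_class: str) -> None:
        if not node_id:
            raise ValueError("empty node identifier")
        existing = self.graph.nodes.get(node_id)
        if existing is not None and existing["node_class"] != node_class:
            raise ValueError(
                f"node {node_id!r} already present with class "
                f"{existing['node_class']!r}, cannot re-add as {node_class!r}")
        self.graph.add_node(node_id, node_class=node_class)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop forbidden: {u!r}")
        for n in (u, v):
            if n not in self.graph:
                raise KeyError(f"node {n!r} must be added before its edges")
        pair = frozenset({self.node_class(u), self.node_class(v)})
        if pair not in self.allowed_pairs:
            raise ValueError(
                f"edge {u!r}-{v!r} joins classes {sorted(pair)}, not allowed")
        self.graph.add_edge(u, v)

    # -- views ------------------------------------------------------------
    def node_class(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["node_class"]

    @property
    def nodes(self) -> dict[str, str]:
        return {n: d["node_class"] for n, d in self.graph.nodes(data=True)}

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges()}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_class(self, node_class: str) -> set[str]:
        return {n for n, c in self.nodes.items() if c == node_class}

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.nodes.values():
            counts[c] = counts.get(c, 0) + 1
        return counts

    def neighbors_of_class(self, node_id: str, node_class: str) -> set[str]:
        return {m for m in self.graph.neighbors(node_id)
                if self.node_class(m) == node_class}

    def validate(self) -> None:
        """Re-scan every edge against the class constraint."""
        for u, v in self.graph.edges():
            pair = frozenset({self.node_class(u), self.node_class(v)})
            if pair not in self.allowed_pairs:
                raise ValueError(f"constraint violated by edge {u!r}-{v!r}")
            if u == v:
                raise ValueError(f"self-loop at {u!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TripartiteNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        cc = self.class_counts()
        parts = ", ".join(f"{v} {k}" for k, v in sorted(cc.items()))
        return (f"<TripartiteNetwork {self.n_nodes} nodes ({parts}), "
                f"{self.n_edges} edges>")


def build_tripartite_network(catalog: InteractionCatalog) -> TripartiteNetwork:
    """Build the miRNA-gene-drug network from an interaction catalog.

    Gene nodes are exactly the disease genes carrying at least one miRNA or
    drug edge; target pairs whose gene is not a disease gene are dropped.
    Genes with a risk score but no interactions never enter the network.
    """
    net = TripartiteNetwork()
    disease = catalog.disease_genes
    for mirna, gene in sorted(catalog.mirna_targets):
        if gene in disease:
            net.add_node(gene, "gene")
            net.add_node(mirna, "miRNA")
            net.add_edge(mirna, gene)
    for drug, gene in sorted(catalog.drug_targets):
        if gene in disease:
            net.add_node(gene, "gene")
            net.add_node(drug, "drug")
            net.add_edge(drug, gene)
    return net


def enumerate_mgdts(net: TripartiteNetwork) -> list[MGDT]:
    """Enumerate every (miRNA, gene, drug) triplet with both edges present.

    The count equals sum over genes of miRNA-degree x drug-degree. Output is
    lexicographic in (miRNA, gene, drug) for reproducibility.
    """
    out: list[MGDT] = []
    for gene in net.nodes_of_class("gene"):
        mirnas = net.neighbors_of_class(gene, "miRNA")
        drugs = net.neighbors_of_class(gene, "drug")
        for m, d in itertools.product(mirnas, drugs):
            out.append(MGDT(m, gene, d))
    out.sort()
    return out


@dataclass
class DegreeStats:
    """Degree distribution, per-class mean degrees, and a top-k node list."""

    distribution: dict[int, int]
    class_means: dict[str, float]
    top_nodes: list[tuple[str, str, int]]  # (node, class, degree)


def degree_stats(net: TripartiteNetwork, k: int = 10) -> DegreeStats:
    """Degree distribution, class mean degrees, and the k highest-degree nodes.

    Class means are averaged over nodes of that class only; a class with no
    nodes is absent from the map. Top-k is sorted by degree descending then
    node id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    degrees = dict(net.graph.degree())
    distribution: dict[int, int] = {}
    for d in degrees.values():
        distribution[d] = distribution.get(d, 0) + 1
    by_class: dict[str, list[int]] = {}
    for n, d in degrees.items():
        by_class.setdefault(net.node_class(n), []).append(d)
    class_means = {c: float(np.mean(v)) for c, v in sorted(by_class.items())}
    ranked = sorted(degrees.items(), key=lambda nd: (-nd[1], nd[0]))
    top = [(n, net.node_class(n), d) for n, d in ranked[:k]]
    return DegreeStats(distribution, class_means, top)


@dataclass
class PowerLawFit:
    slope: float
    intercept: float
    r_squared: float


def fit_power_law(distribution: dict[int, int], *,
                  log_bin: bool = False, n_bins: int = 10) -> PowerLawFit:
    """Least-squares fit of log10(count) on log10(degree).

    Scale-free behaviour shows as a straight line on the log-log degree
    distribution; ``r_squared`` is the usual coefficient of determination of
    that line. By default the raw integer-degree frequencies are used;
    ``log_bin=True`` averages counts inside logarithmically spaced degree
    bins first.
    """
    points = [(d, c) for d, c in distribution.items() if c > 0 and d > 0]
    if log_bin and len(points) >= 3:
        degs = np.array([p[0] for p in points], dtype=float)
        cnts = np.array([p[1] for p in points], dtype=float)
        edges = np.logspace(np.log10(degs.min()), np.log10(degs.max()),
                            n_bins + 1)
        edges[-1] *= 1.0 + 1e-9
        binned = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (degs >= lo) & (degs < hi)
            if mask.any():
                binned.append((float(np.exp(np.mean(np.log(degs[mask])))),
                               float(cnts[mask].mean())))
        points = binned
    if len(points) < 3:
        raise ValueError("underdetermined fit: need >= 3 distinct degrees "
                         "with nonzero counts")
    x = np.log10([p[0] for p in points])
    y = np.log10([p[1] for p in points])
    res = stats.linregress(x, y)
    r2 = float(res.rvalue ** 2)
    return PowerLawFit(float(res.slope), float(res.intercept),
                       min(max(r2, 0.0), 1.0))


def topological_coefficients(net) -> dict[str, float]:
    """Per-node topological coefficient (shared-neighbour redundancy).

    For a node n with degree k_n >= 2, TC(n) is the mean over all nodes
    m != n sharing at least one neighbour with n of J(n, m) / k_n, where
    J(n, m) is the number of shared neighbours, plus one if n and m are
    directly linked. Nodes with k_n < 2 or with no such partner get TC = 0.

    Accepts a :class:`TripartiteNetwork` or any :class:`networkx.Graph`.
    """
    graph = net.graph if isinstance(net, TripartiteNetwork) else net
    adj = {n: set(graph.neighbors(n)) for n in graph.nodes()}
    tc: dict[str, float] = {}
    for n in graph.nodes():
        k_n = len(adj[n])
        if k_n < 2:
            tc[n] = 0.0
            continue
        # candidate partners: nodes at distance 1 or 2 that share a neighbour
        candidates: set = set()
        for nb in adj[n]:
            candidates |= adj[nb]
            candidates.add(nb)
        candidates.discard(n)
        vals = []
        for m in candidates:
            shared = len(adj[n] & adj[m])
            if shared == 0:
                continue
            j = shared + (1 if m in adj[n] else 0)
            vals.append(j / k_n)
        tc[n] = float(np.mean(vals)) if vals else 0.0
    return tc
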