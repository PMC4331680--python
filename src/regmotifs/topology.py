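"""Topological characterisation of coupled motif structures.

Four parameters summarise a merged structure, all computed on the
undirected projection of its constituent motif edges:

* **size** -- node count of the largest connected merged structure;
* **maximum degree** -- highest node degree therein;
* **bridging centrality** BRC(i) = BC(i) x BCO(i), averaged over nodes,
  where BC is unnormalised betweenness (sum over unordered source-target
  pairs, endpoints excluded) and the bridging coefficient is
  BCO(i) = (1/d(i)) / sum_{j in N(i)} 1/d(j);
* **degree centrality** DC(i) = d(i)/(N-1), averaged over nodes.

Bridging nodes sit between densely connected regions; high-degree nodes
concentrate interactions.  The two-group comparison takes per-parameter
medians alpha (group 1) and beta (group 2) and their ratio
gamma = beta/alpha, the contrast used to compare cancer-network
structures against signal-transduction-network structures.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from statistics import median
from typing import Sequence

import networkx as nx

from .cms import CMSStructure

PARAMETERS = ("size", "max_degree", "brc", "dc")


@dataclass(frozen=True)
class TopologyReport:
    """Per-network summary of the largest connected merged structure."""

    network_name: str
    size: int
    max_degree: int
    brc: float
    dc: float

    def parameter(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class GroupComparison:
    """Per-parameter medians for two network groups and their ratio.

    ``gamma[p]`` is ``beta[p] / alpha[p]``, or ``None`` where the group-1
    median is zero (ratio undefined).  ``beta``/``gamma`` are ``None``
    when no second group was supplied.
    """

    alpha: dict[str, float]
    beta: dict[str, float] | None
    gamma: dict[str, float | None] | None


def bridging_coefficient(graph: nx.Graph, node) -> float:
    """BCO(i) = (1/d(i)) / sum over neighbours j of 1/d(j).

    High for nodes of low degree whose neighbours have high degree --
    the signature of a node bridging dense regions.  An isolated node
    returns 0 by convention (with a warning)."""
    d = graph.degree(node)
    if d == 0:
        _warnings.warn(f"bridging coefficient of isolated node {node!r} "
                       "returned as 0", stacklevel=2)
        return 0.0
    denom = sum(1.0 / graph.degree(j) for j in graph[node])
    return (1.0 / d) / denom


def betweenness(graph: nx.Graph, node) -> float:
    """Unnormalised betweenness centrality: the sum over unordered node
    pairs (s, t), both distinct from *node*, of the fraction of s-t
    geodesics passing through it."""
    return betweenness_all(graph)[node]


def betweenness_all(graph: nx.Graph) -> dict:
    return nx.betweenness_centrality(graph, normalized=False)


def bridging_centrality(graph: nx.Graph, node) -> float:
    """BRC(i) = BC(i) x BCO(i)."""
    return betweenness(graph, node) * bridging_coefficient(graph, node)


def degree_centrality(graph: nx.Graph, node) -> float:
    """DC(i) = d(i) / (N - 1) on the undirected projection."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("degree centrality needs at least 2 nodes")
    return graph.degree(node) / (n - 1)


def structure_graph(structure: CMSStructure) -> nx.Graph:
    """Undirected simple projection of a structure's motif edges
    (self-edges dropped, isolated member nodes kept)."""
    g = nx.Graph()
    g.add_nodes_from(sorted(structure.node_set))
    g.add_edges_from((u, v) for u, v in structure.edge_set if u != v)
    return g


def summarize_structures(structures: Sequence[CMSStructure],
                         network_name: str = "") -> TopologyReport:
    """Report on the largest connected merged structure.

    The largest structure is chosen by node count (ties broken
    lexicographically by structure id); size, max degree, mean BRC and
    mean DC are computed over its nodes.  A singleton structure yields
    the degenerate report (max degree 0, BRC 0, DC 0)."""
    if not structures:
        raise ValueError("no structures to summarise")
    largest = min(structures, key=lambda s: (-s.size, s.structure_id))
    g = structure_graph(largest)
    n = g.number_of_nodes()
    if n == 1:
        return TopologyReport(network_name, 1, 0, 0.0, 0.0)
    bc = betweenness_all(g)
    brc = sum(bc[v] * (bridging_coefficient(g, v) if g.degree(v) else 0.0)
              for v in g) / n
    dc = sum(g.degree(v) for v in g) / (n - 1) / n
    return TopologyReport(
        network_name=network_name or largest.structure_id,
        size=n,
        max_degree=max(dict(g.degree).values()),
        brc=brc,
        dc=dc,
    )


def compare_groups(reports_group1: Sequence[TopologyReport],
                   reports_group2: Sequence[TopologyReport] | None = None,
                   ) -> GroupComparison:
    """Per-parameter medians for each group and gamma = beta/alpha.

    With an even count the median is the mean of the central pair.
    gamma is None for a parameter whose alpha is zero; beta and gamma
    are omitted entirely when group 2 is absent or empty."""
    if not reports_group1:
        raise ValueError("group 1 must be non-empty")
    alpha = {p: median(r.parameter(p) for r in reports_group1)
             for p in PARAMETERS}
    if not reports_group2:
        return GroupComparison(alpha=alpha, beta=None, gamma=None)
    beta = {p: median(r.parameter(p) for r in reports_group2)
            for p in PARAMETERS}
    gamma = {p: (beta[p] / alpha[p] if alpha[p] != 0 else None)
             for p in PARAMETERS}
    return GroupComparison(alpha=alpha, beta=beta, gamma=gamma)
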