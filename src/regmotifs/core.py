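"""Signed directed regulatory networks.

A regulatory network is a directed graph whose nodes are bio-molecules
(genes, compounds, miRNAs, transcription factors) and whose edges are
signed regulatory relations: +1 for activation/expression, -1 for
inhibition/repression, 0 when the sign is unknown or the interaction is
compound-mediated.  Edges additionally carry an interaction class
(protein-protein ``PPrel``, gene-expression ``GErel``, protein-compound
``PCrel``, post-translational ``PTM`` or ``other``) and an optional
mechanism tag such as ``phosphorylation``.

Identifiers are upper-cased and compared case-insensitively; KEGG pathway
maps mix cases for the same symbol and downstream set operations
(crosstalk) intersect node sets by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

VALID_SIGNS = (1, -1, 0)
INTERACTION_CLASSES = ("PPrel", "GErel", "PCrel", "PTM", "other")

#: sentinel in :class:`AdjacencyView.sign_matrix` for an (i, j) pair whose
#: parallel edges disagree in sign
SIGN_CONFLICT = 2


@dataclass(frozen=True)
class SignedEdge:
    """A single signed, classed regulatory relation."""

    source: str
    target: str
    sign: int
    interaction_class: str = "other"
    mechanism: str | None = None

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("edge endpoints must be non-empty identifiers")
        if self.sign not in VALID_SIGNS:
            raise ValueError(f"sign must be one of {VALID_SIGNS}, got {self.sign!r}")
        if self.interaction_class not in INTERACTION_CLASSES:
            raise ValueError(f"unknown interaction class {self.interaction_class!r}")

    @property
    def key(self) -> tuple[str, str, int]:
        """Identity triple: at most one edge per (source, target, sign)."""
        return (self.source, self.target, self.sign)


@dataclass
class NetworkNode:
    """A network node: canonical symbol plus alternate symbols."""

    id: str
    kind: str = "gene"  # gene | compound | mirna | tf | group
    aliases: tuple[str, ...] = ()


@dataclass
class RegulatoryNetwork:
    """A named, categorised signed digraph.

    ``edges`` is collapsed so that at most one edge exists per ordered
    (source, target, sign) triple; an ordered pair carrying edges of
    conflicting sign keeps both (sign is part of edge identity) and is
    flagged in ``warnings``.  Self-edges are permitted -- they encode
    auto-regulation loops.
    """

    name: str
    category: str = "other"  # cancer | stn | other
    nodes: dict[str, NetworkNode] = field(default_factory=dict)
    edges: list[SignedEdge] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    _edge_keys: set[tuple[str, str, int]] = field(default_factory=set, repr=False)
    _succ: dict[str, set[str]] = field(default_factory=dict, repr=False)
    _pred: dict[str, set[str]] = field(default_factory=dict, repr=False)

    # -- construction -------------------------------------------------

    def add_node(self, node_id: str, kind: str = "gene",
                 aliases: Iterable[str] = ()) -> NetworkNode:
        node_id = canonical_id(node_id)
        existing = self.nodes.get(node_id)
        if existing is not None:
            merged = tuple(dict.fromkeys(existing.aliases + tuple(aliases)))
            existing.aliases = merged
            return existing
        node = NetworkNode(node_id, kind, tuple(aliases))
        self.nodes[node_id] = node
        self._succ.setdefault(node_id, set())
        self._pred.setdefault(node_id, set())
        return node

    def add_edge(self, source: str, target: str, sign: int,
                 interaction_class: str = "other",
                 mechanism: str | None = None) -> SignedEdge | None:
        """Add an edge, collapsing exact (source, target, sign) duplicates.

        Returns the stored edge, or ``None`` when the triple was already
        present.  A new edge whose ordered pair already carries a
        different sign is kept and flagged as ambiguous.
        """
        source = canonical_id(source)
        target = canonical_id(target)
        edge = SignedEdge(source, target, sign, interaction_class, mechanism)
        if edge.key in self._edge_keys:
            return None
        prior = {s for s in VALID_SIGNS if (source, target, s) in self._edge_keys}
        if prior:
            self.warnings.append(
                f"ambiguous sign for {source}->{target}: "
                f"{sorted(prior | {sign})}"
            )
        self.add_node(source)
        self.add_node(target)
        self.edges.append(edge)
        self._edge_keys.add(edge.key)
        self._succ[source].add(target)
        self._pred[target].add(source)
        return edge

    # -- queries ------------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        """Node identifiers in the canonical (lexicographic) order."""
        return sorted(self.nodes)

    def has_edge(self, source: str, target: str) -> bool:
        return target in self._succ.get(canonical_id(source), ())

    def successors(self, node: str) -> set[str]:
        return set(self._succ.get(canonical_id(node), ()))

    def predecessors(self, node: str) -> set[str]:
        return set(self._pred.get(canonical_id(node), ()))

    def edge_sign(self, source: str, target: str) -> int | None:
        """Sign of source->target: +1/-1/0, or ``None`` when parallel
        edges conflict.  Raises ``KeyError`` when no edge exists."""
        source, target = canonical_id(source), canonical_id(target)
        signs = {s for s in VALID_SIGNS if (source, target, s) in self._edge_keys}
        if not signs:
            raise KeyError(f"no edge {source}->{target}")
        if len(signs) == 1:
            return next(iter(signs))
        return None

    def edge_list(self) -> list[tuple[str, str, int]]:
        return sorted(e.key for e in self.edges)

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.node_ids)

    # -- conversions --------------------------------------------------

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(name=self.name)
        for nid in self.node_ids:
            node = self.nodes[nid]
            g.add_node(nid, kind=node.kind)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign,
                       interaction_class=e.interaction_class)
        return g


def canonical_id(identifier: str) -> str:
    ident = str(identifier).strip().upper()
    if not ident:
        raise ValueError("empty node identifier")
    return ident


def build_network(
    name: str,
    edges: Iterable[Sequence] = (),
    category: str = "other",
) -> RegulatoryNetwork:
    """Build a :class:`RegulatoryNetwork` from edge tuples.

    Each tuple is ``(source, target, sign)`` optionally followed by an
    interaction class and a mechanism tag.  Nodes are inferred from edge
    endpoints; exact duplicate triples collapse to one edge; same-pair
    edges of conflicting sign are both retained and flagged.
    """
    if not name:
        raise ValueError("network name must be non-empty")
    net = RegulatoryNetwork(name=name, category=category)
    for tup in edges:
        if len(tup) < 3 or len(tup) > 5:
            raise ValueError(f"malformed edge tuple {tup!r}")
        source, target, sign = tup[0], tup[1], tup[2]
        try:
            sign = int(sign)
        except (TypeError, ValueError):
            raise ValueError(f"malformed sign {tup[2]!r} in edge {tup!r}") from None
        cls = tup[3] if len(tup) > 3 else "other"
        mech = tup[4] if len(tup) > 4 else None
        net.add_edge(source, target, sign, cls, mech)
    return net


@dataclass
class AdjacencyView:
    """Dense adjacency snapshot with a stable lexicographic node order.

    ``matrix[i, j]`` is True iff an edge ordering[i] -> ordering[j] of any
    sign exists; the diagonal marks self-regulation.  ``sign_matrix``
    holds the edge sign where ``matrix`` is True (``SIGN_CONFLICT`` when
    parallel edges disagree) and 0 elsewhere.
    """

    ordering: list[str]
    matrix: np.ndarray
    sign_matrix: np.ndarray

    def index(self, node: str) -> int:
        return self.ordering.index(canonical_id(node))

    def edge_set(self) -> set[tuple[str, str]]:
        rows, cols = np.nonzero(self.matrix)
        return {(self.ordering[i], self.ordering[j]) for i, j in zip(rows, cols)}


def to_adjacency(net: RegulatoryNetwork) -> AdjacencyView:
    """Dense adjacency view of *net* (nodes ordered lexicographically)."""
    ordering = net.node_ids
    idx = {n: i for i, n in enumerate(ordering)}
    n = len(ordering)
    matrix = np.zeros((n, n), dtype=bool)
    signs = np.zeros((n, n), dtype=np.int8)
    for e in net.edges:
        i, j = idx[e.source], idx[e.target]
        if matrix[i, j] and signs[i, j] != e.sign:
            signs[i, j] = SIGN_CONFLICT
        else:
            signs[i, j] = e.sign
        matrix[i, j] = True
    return AdjacencyView(ordering=ordering, matrix=matrix, sign_matrix=signs)


def undirected_projection(net: RegulatoryNetwork) -> nx.Graph:
    """Undirected simple graph: {u, v} present iff u->v or v->u, u != v.

    Self-edges are dropped.  All nodes are kept, including isolates.
    """
    g = nx.Graph()
    g.add_nodes_from(net.node_ids)
    for e in net.edges:
        if e.source != e.target:
            g.add_edge(e.source, e.target)
    return g


# -- edge-list TSV ----------------------------------------------------

_SIGN_TO_TEXT = {1: "+1", -1: "-1", 0: "0"}
_TEXT_TO_SIGN = {"+1": 1, "1": 1, "-1": -1, "0": 0}


def write_edgelist(net: RegulatoryNetwork, path: str | Path) -> None:
    """Write the plain signed edge-list TSV (one edge per line:
    source, target, sign, class)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for e in net.edges:
            fh.write(f"{e.source}\t{e.target}\t{_SIGN_TO_TEXT[e.sign]}"
                     f"\t{e.interaction_class}\n")


def read_edgelist(path: str | Path, name: str | None = None,
                  category: str = "other") -> RegulatoryNetwork:
    """Read the signed edge-list TSV; ``#`` lines are comments."""
    path = Path(path)
    tuples = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path.name}:{lineno}: malformed edge line {line!r}")
            if parts[2] not in _TEXT_TO_SIGN:
                raise ValueError(f"{path.name}:{lineno}: malformed sign {parts[2]!r}")
            cls = parts[3] if len(parts) > 3 else "other"
            tuples.append((parts[0], parts[1], _TEXT_TO_SIGN[parts[2]], cls))
    return build_network(name or path.stem, tuples, category=category)
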