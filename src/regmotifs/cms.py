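"""Coupled motif structures (CMS).

Motifs rarely act alone: instances that share genes interlock into
larger subnetworks.  Two motif instances are *coupled* when their node
sets intersect; transitively merging coupled instances yields the
coupled motif structures, reconstructing the global architecture of a
pathway bottom-up from its motifs.

Merging is computed as connected components of the instance-overlap
graph (instances adjacent iff they share at least one node) -- the
fixpoint of repeatedly merging any two overlapping structures, but
order-independent and near-linear.

The six-type coupling table counts unordered instance pairs that share
at least one node, restricted to FBL/FFL/bi-fan combinations: FBL-FBL,
FFL-FFL, bi-fan-bi-fan, FBL-FFL, FBL-bi-fan and FFL-bi-fan.  ARL and
SIM instances still participate in merged structures (and downstream
overlays), just not in this pair table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .core import RegulatoryNetwork, build_network
from .motifs import BIFAN, FBL, FFL, MotifInstance

#: the six unordered type pairs of the coupling count table
COUPLING_PAIRS = (
    (FBL, FBL), (FFL, FFL), (BIFAN, BIFAN),
    (FBL, FFL), (FBL, BIFAN), (FFL, BIFAN),
)


@dataclass(frozen=True)
class CMSStructure:
    """One merged structure: its member instances, the union of their
    nodes and the union of their constituent directed edges (with merged
    signs; a sign conflict between members becomes ``None``)."""

    structure_id: str
    member_instances: tuple[MotifInstance, ...]
    node_set: frozenset[str]
    edge_set: frozenset[tuple[str, str]]
    edge_signs: tuple[tuple[tuple[str, str], int | None], ...]

    @property
    def size(self) -> int:
        return len(self.node_set)

    @property
    def member_types(self) -> tuple[str, ...]:
        return tuple(i.motif_type for i in self.member_instances)


def count_coupled_pairs(instances: Sequence[MotifInstance]) -> dict[tuple[str, str], int]:
    """Count, for each of the six type pairs, the unordered instance
    pairs sharing >= 1 node.  A pair is counted once however many nodes
    it shares."""
    counts = {pair: 0 for pair in COUPLING_PAIRS}
    relevant = [i for i in instances if i.motif_type in (FBL, FFL, BIFAN)]
    for a, b in combinations(relevant, 2):
        if a.node_set & b.node_set:
            key = tuple(sorted((a.motif_type, b.motif_type),
                               key=(FBL, FFL, BIFAN).index))
            counts[key] += 1
    return counts


def _merged_structure(structure_id: str,
                      members: Sequence[MotifInstance]) -> CMSStructure:
    nodes: set[str] = set()
    signs: dict[tuple[str, str], int | None] = {}
    conflicted: set[tuple[str, str]] = set()
    for inst in members:
        nodes |= set(inst.nodes)
        for edge, s in inst.edge_signs:
            if edge in signs and signs[edge] != s:
                conflicted.add(edge)
            signs.setdefault(edge, s)
    for edge in conflicted:
        signs[edge] = None
    return CMSStructure(
        structure_id=structure_id,
        member_instances=tuple(members),
        node_set=frozenset(nodes),
        edge_set=frozenset(signs),
        edge_signs=tuple(sorted(signs.items())),
    )


def merge_cms(instances: Sequence[MotifInstance],
              include_singletons: bool = True) -> list[CMSStructure]:
    """Merge overlapping instances into coupled motif structures.

    Emits one structure per connected component of the instance-overlap
    graph; components are maximal, so no two emitted structures share a
    node through any member.  Singleton components (an instance coupled
    to nothing) are kept unless *include_singletons* is False.  Output
    order and structure ids are deterministic (sorted by the smallest
    member node tuple)."""
    overlap = nx.Graph()
    overlap.add_nodes_from(range(len(instances)))
    by_node: dict[str, list[int]] = {}
    for i, inst in enumerate(instances):
        for n in inst.nodes:
            by_node.setdefault(n, []).append(i)
    for members in by_node.values():
        for i, j in zip(members, members[1:]):
            overlap.add_edge(i, j)

    components = []
    for comp in nx.connected_components(overlap):
        members = sorted((instances[i] for i in comp), key=lambda m: m.sort_key)
        if len(members) < 2 and not include_singletons:
            continue
        components.append(members)
    components.sort(key=lambda ms: ms[0].sort_key)
    return [
        _merged_structure(f"cms-{k:04d}", members)
        for k, members in enumerate(components, start=1)
    ]


def cms_graph(structure: CMSStructure,
              name: str | None = None) -> RegulatoryNetwork:
    """Subnetwork induced by the structure's constituent motif edges only
    (not all induced edges of the parent network).  An edge whose member
    signs conflict is carried with sign 0."""
    tuples = [(u, v, 0 if s is None else s)
              for (u, v), s in structure.edge_signs]
    net = build_network(name or structure.structure_id, tuples)
    for n in structure.node_set:  # keep isolated members (e.g. a bare ARL node)
        net.add_node(n)
    return net


def write_cms_report(structures: Iterable[CMSStructure], path) -> None:
    """Per-network CMS report TSV: id, member count, member types, nodes."""
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("structure_id\tn_members\tmember_types\tnodes\n")
        for s in structures:
            fh.write(f"{s.structure_id}\t{len(s.member_instances)}"
                     f"\t{','.join(s.member_types)}"
                     f"\t{','.join(sorted(s.node_set))}\n")
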