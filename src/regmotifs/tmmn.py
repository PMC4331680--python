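"""TF-miRNA-motif networks (TMMN).

Motif genes sit inside a wider regulatory hierarchy: transcription
factors initiate miRNA transcription (TF -> miRNA), and miRNAs repress
motif genes post-transcriptionally (miRNA -> gene).  Overlaying
experimentally validated TF->miRNA and miRNA->target tables onto a motif
inventory yields a three-layer graph -- the TMMN -- whose gene layer is
the motif/CMS subnetwork, annotated with oncogene (OCG) / tumour
suppressor (TSG) roles.

miRNA regulation of a motif type is classified as *inter-motif* (one
miRNA targeting genes of two or more distinct instances) or
*intra-motif* (one miRNA targeting two or more member genes of a single
instance); a miRNA may count as both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .cms import CMSStructure
from .core import RegulatoryNetwork, canonical_id
from .motifs import BIFAN, FBL, FFL, MOTIF_TYPES, MotifInstance

ROLE_PRECEDENCE = ("OCG", "TSG", "cancer-related", "unknown")

LAYER_TF = "tf"
LAYER_MIRNA = "mirna"
LAYER_GENE = "gene"


def normalize_mirna(name: str) -> str:
    """Matching key for a miRNA name: case-insensitive, species prefix
    ``hsa-`` stripped.  Display names keep their original spelling."""
    key = str(name).strip().lower()
    if key.startswith("hsa-"):
        key = key[4:]
    if not key:
        raise ValueError("empty miRNA identifier")
    return key


@dataclass
class OverlayTables:
    """Deduplicated regulation overlays, identifier-normalised.

    ``mirna_targets`` holds (miRNA key, gene) pairs, ``tf_mirna``
    (TF, miRNA key) pairs; ``mirna_display`` maps keys back to the first
    spelling seen.  ``gene_roles`` maps genes to OCG/TSG/cancer-related.
    """

    mirna_targets: set[tuple[str, str]] = field(default_factory=set)
    tf_mirna: set[tuple[str, str]] = field(default_factory=set)
    gene_roles: dict[str, str] = field(default_factory=dict)
    mirna_display: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_mirna_target(self, mirna: str, gene: str) -> None:
        key = normalize_mirna(mirna)
        self.mirna_display.setdefault(key, str(mirna).strip())
        self.mirna_targets.add((key, canonical_id(gene)))

    def add_tf_mirna(self, tf: str, mirna: str) -> None:
        key = normalize_mirna(mirna)
        self.mirna_display.setdefault(key, str(mirna).strip())
        self.tf_mirna.add((canonical_id(tf), key))

    def add_gene_role(self, gene: str, role: str) -> None:
        gene = canonical_id(gene)
        role = role.strip()
        if role not in ROLE_PRECEDENCE:
            raise ValueError(f"unknown gene role {role!r}")
        current = self.gene_roles.get(gene)
        if current is None or current == role:
            self.gene_roles[gene] = role
            return
        winner = min(current, role, key=ROLE_PRECEDENCE.index)
        self.warnings.append(
            f"conflicting roles for {gene}: {current} vs {role}; kept {winner}")
        self.gene_roles[gene] = winner

    def targets_of(self, mirna_key: str) -> set[str]:
        return {g for m, g in self.mirna_targets if m == mirna_key}

    def role_of(self, gene: str) -> str:
        return self.gene_roles.get(canonical_id(gene), "unknown")


def _read_pairs(path: Path, label: str):
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(
                    f"{path.name}:{lineno}: malformed {label} line {line!r}")
            yield parts[0], parts[1]


def load_overlays(mirna_target_file, tf_mirna_file,
                  gene_role_file) -> OverlayTables:
    """Read the three overlay TSVs (miRNA->gene, TF->miRNA, gene role).

    Pairs are deduplicated after identifier normalisation.  A gene
    listed under several roles keeps the highest-precedence one
    (OCG > TSG > cancer-related) with a warning.  A malformed line
    raises with its file and line number."""
    tables = OverlayTables()
    for mirna, gene in _read_pairs(Path(mirna_target_file), "miRNA-target"):
        tables.add_mirna_target(mirna, gene)
    for tf, mirna in _read_pairs(Path(tf_mirna_file), "TF-miRNA"):
        tables.add_tf_mirna(tf, mirna)
    for gene, role in _read_pairs(Path(gene_role_file), "gene-role"):
        tables.add_gene_role(gene, role)
    return tables


@dataclass(frozen=True)
class MirnaRegulationSummary:
    """Per-type inter/intra miRNA counts plus the total number of
    distinct miRNAs touching any motif gene."""

    inter: dict[str, int]
    intra: dict[str, int]
    total_mirnas: int

    def as_strings(self) -> dict[str, str]:
        """The conventional "inter/intra" rendering per motif type."""
        return {t: f"{self.inter[t]}/{self.intra[t]}" for t in MOTIF_TYPES}


def classify_mirna_regulation(instances: Sequence[MotifInstance],
                              overlays: OverlayTables,
                              ) -> MirnaRegulationSummary:
    """Classify each miRNA's regulation of each motif type.

    For type T, a miRNA is inter-counted when its targets hit >= 2
    distinct instances of T, and intra-counted when it targets >= 2
    member genes of one instance of T; the two counts are not exclusive.
    """
    motif_genes: set[str] = set()
    for inst in instances:
        motif_genes |= inst.node_set
    by_type: dict[str, list[frozenset[str]]] = {t: [] for t in MOTIF_TYPES}
    for inst in instances:
        by_type[inst.motif_type].append(inst.node_set)

    inter = {t: 0 for t in MOTIF_TYPES}
    intra = {t: 0 for t in MOTIF_TYPES}
    total = 0
    for key in sorted({m for m, _ in overlays.mirna_targets}):
        targets = overlays.targets_of(key)
        if not (targets & motif_genes):
            continue
        total += 1
        for t, node_sets in by_type.items():
            hit = [ns for ns in node_sets if ns & targets]
            if len(hit) >= 2:
                inter[t] += 1
            if any(len(ns & targets) >= 2 for ns in hit):
                intra[t] += 1
    return MirnaRegulationSummary(inter=inter, intra=intra, total_mirnas=total)


def build_tmmn(net: RegulatoryNetwork,
               instances_or_cms: Sequence[MotifInstance] | Sequence[CMSStructure],
               overlays: OverlayTables) -> nx.DiGraph:
    """Assemble the three-layer TF -> miRNA -> motif-gene graph.

    The gene layer is the union of the supplied motif instances' (or CMS
    structures') nodes and constituent edges.  miRNAs enter only when
    they target >= 1 gene-layer node; TFs only when they regulate an
    included miRNA.  Gene nodes carry OCG/TSG role labels.  Across
    layers the graph is a DAG (no edge re-enters an upper layer);
    gene->gene edges may of course be cyclic.
    """
    g = nx.DiGraph(name=f"tmmn:{net.name}")

    gene_edges: dict[tuple[str, str], int | None] = {}
    gene_nodes: set[str] = set()
    for item in instances_or_cms:
        gene_nodes |= set(item.node_set if isinstance(item, CMSStructure)
                          else item.nodes)
        for edge, s in item.edge_signs:
            gene_edges.setdefault(edge, s)
    for node in sorted(gene_nodes):
        kind = net.nodes[node].kind if node in net.nodes else "gene"
        g.add_node(node, layer=LAYER_GENE, kind=kind,
                   role=overlays.role_of(node))
    for (u, v), s in sorted(gene_edges.items()):
        g.add_edge(u, v, kind="gene-gene", sign=0 if s is None else s)

    included_mirnas = []
    for key in sorted({m for m, _ in overlays.mirna_targets}):
        hits = sorted(overlays.targets_of(key) & gene_nodes)
        if not hits:
            continue
        display = overlays.mirna_display[key]
        included_mirnas.append(key)
        g.add_node(display, layer=LAYER_MIRNA, kind="mirna", role="unknown")
        for gene in hits:
            g.add_edge(display, gene, kind="mirna-gene", sign=-1)

    for tf, key in sorted(overlays.tf_mirna):
        if key not in included_mirnas:
            continue
        display = overlays.mirna_display[key]
        if tf not in g:
            g.add_node(tf, layer=LAYER_TF, kind="tf", role="unknown")
        g.add_edge(tf, display, kind="tf-mirna", sign=1)
    return g


def trace_paths(tmmn: nx.DiGraph, source: str, sink: str,
                cutoff: int = 6) -> list[list[str]]:
    """All simple directed paths from *source* to *sink* up to *cutoff*
    edges, lexicographically ordered.  A node identical to itself yields
    the trivial path."""
    if source not in tmmn or sink not in tmmn:
        missing = source if source not in tmmn else sink
        raise KeyError(f"node {missing!r} not in TMMN")
    if source == sink:
        return [[source]]
    return sorted(nx.all_simple_paths(tmmn, source, sink, cutoff=cutoff))


def write_graphml(tmmn: nx.DiGraph, path) -> None:
    nx.write_graphml(tmmn, str(path))


def write_sif(tmmn: nx.DiGraph, sif_path, attrs_path=None) -> None:
    """SIF export (source <TAB> edge kind <TAB> target) plus an optional
    node-attribute TSV (node, layer, kind, role) for network viewers."""
    sif_path = Path(sif_path)
    with sif_path.open("w", encoding="utf-8", newline="\n") as fh:
        for u, v, data in sorted(tmmn.edges(data=True)):
            fh.write(f"{u}\t{data.get('kind', 'edge')}\t{v}\n")
    if attrs_path is not None:
        with Path(attrs_path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("node\tlayer\tkind\trole\n")
            for n, data in sorted(tmmn.nodes(data=True)):
                fh.write(f"{n}\t{data.get('layer', '')}\t"
                         f"{data.get('kind', '')}\t{data.get('role', '')}\n")
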