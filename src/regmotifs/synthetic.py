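"""Synthetic networks, planted motifs, KGML fixtures and overlay tables.

Everything a test or demonstration needs is generated here, seeded and
deterministic: Erdos-Renyi style signed digraphs, networks with motifs
planted on disjoint node groups, minimal KGML documents, and random
three-layer overlay tables.  The module also houses the brute-force
motif enumerator used as the independent oracle against the production
finders (it applies each motif definition literally over all node tuples
of the relevant arity, so it is only sensible for small n).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from itertools import combinations, permutations
from pathlib import Path

from .core import RegulatoryNetwork, build_network
from .motifs import (ARL, BIFAN, FBL, FFL, SIM, DEFAULT_CONFIG,
                     MotifInstance, MotifSearchConfig, classify_ffl)
from .tmmn import OverlayTables

_ROLES = ("OCG", "TSG", "cancer-related", "unknown")


def random_signed_digraph(n: int, p: float, sign_p: float = 0.8,
                          seed: int = 0, self_loops: bool = False,
                          name: str = "random",
                          category: str = "other") -> RegulatoryNetwork:
    """Signed Erdos-Renyi digraph: each ordered pair (and each self-pair
    when *self_loops*) carries an edge with probability *p*, activating
    with probability *sign_p*.  Same seed, same network."""
    if n < 1:
        raise ValueError("need n >= 1")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    rng = random.Random(seed)
    ids = [f"G{i:03d}" for i in range(n)]
    tuples = []
    for u in ids:
        for v in ids:
            if u == v and not self_loops:
                continue
            if rng.random() < p:
                sign = 1 if rng.random() < sign_p else -1
                tuples.append((u, v, sign, "PPrel"))
    net = build_network(name, tuples, category=category)
    for i in ids:
        net.add_node(i)
    return net


@dataclass(frozen=True)
class PlantSpec:
    """How many instances of each motif type to plant, on how many
    nodes, over what background edge density."""

    n_nodes: int
    n_arl: int = 0
    n_fbl: int = 0
    n_ffl: int = 0
    n_bifan: int = 0
    n_sim: int = 0
    sim_targets: int = 3
    background_p: float = 0.0
    sign_p: float = 1.0
    seed: int = 0

    @property
    def node_demand(self) -> int:
        return (self.n_arl + 2 * self.n_fbl + 3 * self.n_ffl
                + 4 * self.n_bifan + self.n_sim * (1 + self.sim_targets))

    def __post_init__(self) -> None:
        if not 0 <= self.background_p <= 1 or not 0 <= self.sign_p <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_arl, self.n_fbl, self.n_ffl,
               self.n_bifan, self.n_sim) < 0:
            raise ValueError("planted counts must be non-negative")


def plant_motifs(spec: PlantSpec,
                 name: str = "planted",
                 category: str = "other",
                 node_ids: list[str] | None = None,
                 ) -> tuple[RegulatoryNetwork, list[MotifInstance]]:
    """Plant the requested motifs on disjoint node groups, then sprinkle
    background edges.

    With ``background_p == 0`` the finders (at SIM threshold
    ``sim_targets``) recover exactly the returned ground truth.
    Background edges never touch pairs that would mutate a planted
    instance: no self-loop background, no edge within a planted bi-fan's
    regulator pair, and no extra out-edge from a planted SIM master --
    so at any background density the finders' output is a superset of
    the ground truth.

    *node_ids*, when given, supplies the gene symbols (at least
    ``n_nodes`` of them, used in sorted order); this lets collections of
    planted networks share a gene universe so their motif node sets
    overlap partially, as pathway maps do.
    """
    if spec.node_demand > spec.n_nodes:
        raise ValueError(
            f"{spec.node_demand} nodes needed to plant, only {spec.n_nodes} available")
    rng = random.Random(spec.seed)

    def draw_sign() -> int:
        return 1 if rng.random() < spec.sign_p else -1

    if node_ids is not None:
        if len(node_ids) < spec.n_nodes:
            raise ValueError(f"need {spec.n_nodes} node ids, got {len(node_ids)}")
        ids = sorted(node_ids)[: spec.n_nodes]
    else:
        ids = [f"M{i:03d}" for i in range(spec.n_nodes)]
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        group = ids[cursor:cursor + k]
        cursor += k
        return group

    tuples: list[tuple[str, str, int, str]] = []
    truth: list[MotifInstance] = []
    forbidden: set[tuple[str, str]] = set()
    sim_masters: set[str] = set()

    def plant(edges: list[tuple[str, str]]) -> dict[tuple[str, str], int]:
        signs = {}
        for u, v in edges:
            s = draw_sign()
            signs[(u, v)] = s
            tuples.append((u, v, s, "PPrel"))
        return signs

    for _ in range(spec.n_arl):
        (a,) = take(1)
        signs = plant([(a, a)])
        truth.append(MotifInstance(ARL, (a,), tuple(signs.items())))
    for _ in range(spec.n_fbl):
        a, b = sorted(take(2))
        signs = plant([(a, b), (b, a)])
        truth.append(MotifInstance(FBL, (a, b), tuple(signs.items())))
    for _ in range(spec.n_ffl):
        x, y, z = take(3)
        signs = plant([(x, y), (y, z), (x, z)])
        inst = MotifInstance(FFL, (x, y, z), tuple(signs.items()))
        truth.append(replace(inst, coherence=classify_ffl(inst)))
    for _ in range(spec.n_bifan):
        r1, r2, t1, t2 = take(4)
        (r1, r2), (t1, t2) = sorted((r1, r2)), sorted((t1, t2))
        signs = plant([(r1, t1), (r1, t2), (r2, t1), (r2, t2)])
        truth.append(MotifInstance(BIFAN, (r1, r2, t1, t2),
                                   tuple(signs.items())))
        forbidden |= {(r1, r2), (r2, r1)}
    for _ in range(spec.n_sim):
        group = take(1 + spec.sim_targets)
        master, targets = group[0], sorted(group[1:])
        signs = plant([(master, t) for t in targets])
        truth.append(MotifInstance(SIM, (master, *targets),
                                   tuple(sorted(signs.items()))))
        sim_masters.add(master)

    planted_pairs = {(u, v) for u, v, _, _ in tuples}
    if spec.background_p > 0:
        for u in ids:
            if u in sim_masters:
                continue
            for v in ids:
                if u == v or (u, v) in planted_pairs or (u, v) in forbidden:
                    continue
                if rng.random() < spec.background_p:
                    tuples.append((u, v, draw_sign(), "PPrel"))

    net = build_network(name, tuples, category=category)
    for i in ids:
        net.add_node(i)
    truth.sort(key=lambda inst: inst.sort_key)
    return net, truth


#: (name, category, spec-template) rows of the demonstration collection
_COLLECTION_SPECS = (
    ("cancer-a", "cancer", dict(n_nodes=24, n_ffl=2, n_bifan=2, n_sim=1)),
    ("cancer-b", "cancer", dict(n_nodes=20, n_fbl=1, n_ffl=1, n_bifan=1)),
    ("stn-a", "stn", dict(n_nodes=26, n_ffl=1, n_bifan=3, n_sim=1)),
    ("stn-b", "stn", dict(n_nodes=18, n_arl=1, n_fbl=1, n_ffl=2)),
)


def fixture_collection(seed: int = 0, universe_size: int = 60,
                       background_p: float = 0.03, sign_p: float = 0.8,
                       ) -> list[tuple[RegulatoryNetwork, list[MotifInstance]]]:
    """A small two-group demonstration collection (two cancer-category,
    two stn-category planted networks) drawing genes from one shared
    universe, so motif node sets overlap partially across networks --
    the situation the crosstalk matrix is meant to quantify."""
    rng = random.Random(seed)
    universe = [f"GENE{i:02d}" for i in range(universe_size)]
    out = []
    for k, (name, category, template) in enumerate(_COLLECTION_SPECS):
        spec = PlantSpec(background_p=background_p, sign_p=sign_p,
                         seed=seed + k, **template)
        ids = rng.sample(universe, spec.n_nodes)
        out.append(plant_motifs(spec, name=name, category=category,
                                node_ids=ids))
    return out


def brute_force_enumerate(net: RegulatoryNetwork, motif_type: str,
                          config: MotifSearchConfig = DEFAULT_CONFIG,
                          ) -> list[MotifInstance]:
    """Exhaustive oracle: apply the motif definition literally over all
    node tuples of the relevant arity.  Independent of the production
    finders; intended for n <= ~30."""
    ids = net.node_ids
    has = net.has_edge
    out: list[MotifInstance] = []

    def sig(edges):
        return tuple((e, net.edge_sign(*e)) for e in edges)

    if motif_type == ARL:
        out = [MotifInstance(ARL, (n,), sig(((n, n),)))
               for n in ids if has(n, n)]
    elif motif_type == FBL:
        for a, b in combinations(ids, 2):
            if has(a, b) and has(b, a):
                out.append(MotifInstance(FBL, (a, b), sig(((a, b), (b, a)))))
    elif motif_type == FFL:
        if config.ffl_style == "bidirectional":
            for trio in combinations(ids, 3):
                if all(has(u, v) for u, v in permutations(trio, 2)):
                    inst = MotifInstance(
                        FFL, trio,
                        sig(tuple(permutations(trio, 2))))
                    out.append(replace(inst, coherence=classify_ffl(inst)))
        else:
            for x, y, z in permutations(ids, 3):
                if has(x, y) and has(y, z) and has(x, z):
                    inst = MotifInstance(FFL, (x, y, z),
                                         sig(((x, y), (y, z), (x, z))))
                    out.append(replace(inst, coherence=classify_ffl(inst)))
    elif motif_type == BIFAN:
        for r1, r2 in combinations(ids, 2):
            if has(r1, r2) or has(r2, r1):
                continue
            for t1, t2 in combinations(ids, 2):
                if {t1, t2} & {r1, r2}:
                    continue
                if not (has(r1, t1) and has(r1, t2)
                        and has(r2, t1) and has(r2, t2)):
                    continue
                if config.bifan_exclude_target_edges and (
                        has(t1, t2) or has(t2, t1)):
                    continue
                out.append(MotifInstance(
                    BIFAN, (r1, r2, t1, t2),
                    sig(((r1, t1), (r1, t2), (r2, t1), (r2, t2)))))
    elif motif_type == SIM:
        for master in ids:
            targets = sorted(t for t in ids
                             if t != master and has(master, t))
            if len(targets) >= config.sim_min_targets:
                out.append(MotifInstance(
                    SIM, (master, *targets),
                    sig(tuple((master, t) for t in targets))))
    else:
        raise ValueError(f"unknown motif type {motif_type!r}")
    out.sort(key=lambda inst: inst.sort_key)
    return out


def make_overlay_fixture(net: RegulatoryNetwork, n_mirnas: int,
                         n_tfs: int, seed: int = 0,
                         targets_per_mirna: int = 2) -> OverlayTables:
    """Random overlay tables over *net*'s nodes: each miRNA targets
    *targets_per_mirna* distinct network genes, each TF regulates one or
    more miRNAs, and genes get random cancer-role labels."""
    if len(net) < 1:
        raise ValueError("network must have at least one node")
    rng = random.Random(seed)
    genes = net.node_ids
    tables = OverlayTables()
    mirnas = [f"hsa-miR-{i + 1:02d}" for i in range(n_mirnas)]
    for m in mirnas:
        k = min(targets_per_mirna, len(genes))
        for g in rng.sample(genes, k):
            tables.add_mirna_target(m, g)
    for i in range(n_tfs):
        tf = f"TF{i + 1:02d}"
        if mirnas:
            for m in rng.sample(mirnas, 1 + rng.randrange(len(mirnas))):
                tables.add_tf_mirna(tf, m)
    for g in genes:
        role = rng.choice(_ROLES)
        if role != "unknown":
            tables.add_gene_role(g, role)
    return tables


def write_kgml_fixture(net: RegulatoryNetwork, path) -> None:
    """Serialise a gene network as a minimal KGML document (entries with
    graphics labels, PPrel relations with activation/inhibition
    subtypes; sign-0 edges get no signed subtype).  Parsing the result
    recovers the same node and signed-edge sets."""
    ids = net.node_ids
    idx = {n: str(i + 1) for i, n in enumerate(ids)}
    lines = [f'<pathway name="path:{net.name}" title="{net.name}">']
    for n in ids:
        kind = net.nodes[n].kind
        kind = kind if kind in ("gene", "compound") else "gene"
        lines.append(f'  <entry id="{idx[n]}" name="{n}" type="{kind}">')
        lines.append(f'    <graphics name="{n}"/>')
        lines.append("  </entry>")
    for e in net.edges:
        lines.append(f'  <relation entry1="{idx[e.source]}" '
                     f'entry2="{idx[e.target]}" type="PPrel">')
        if e.sign == 1:
            lines.append('    <subtype name="activation" value="--&gt;"/>')
        elif e.sign == -1:
            lines.append('    <subtype name="inhibition" value="--|"/>')
        else:
            lines.append('    <subtype name="binding/association" value="---"/>')
        lines.append("  </relation>")
    lines.append("</pathway>")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_overlay_files(tables: OverlayTables, directory) -> dict[str, Path]:
    """Write the three overlay TSVs; returns their paths keyed by kind."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_targets": directory / "mirna_targets.tsv",
        "tf_mirna": directory / "tf_mirna.tsv",
        "gene_roles": directory / "gene_roles.tsv",
    }
    with paths["mirna_targets"].open("w", encoding="utf-8", newline="\n") as fh:
        for key, gene in sorted(tables.mirna_targets):
            fh.write(f"{tables.mirna_display[key]}\t{gene}\n")
    with paths["tf_mirna"].open("w", encoding="utf-8", newline="\n") as fh:
        for tf, key in sorted(tables.tf_mirna):
            fh.write(f"{tf}\t{tables.mirna_display[key]}\n")
    with paths["gene_roles"].open("w", encoding="utf-8", newline="\n") as fh:
        for gene, role in sorted(tables.gene_roles.items()):
            fh.write(f"{gene}\t{role}\n")
    return paths
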