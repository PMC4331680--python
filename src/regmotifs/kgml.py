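"""KGML (KEGG pathway XML) parsing into signed regulatory networks.

KEGG pathway maps encode molecules as ``entry`` elements (gene, compound,
group, map) and regulation as ``relation`` elements whose ``subtype``
children carry the semantics: activation/expression map to sign +1,
inhibition/repression to -1, phosphorylation events are recorded as a
post-translational-modification mechanism with the accompanying sign,
and compound-mediated relations become sign-0 PCrel edges between the
two protein endpoints.  Group entries are expanded so each member
inherits all edges incident to the group; ``map`` placeholder entries
are dropped.  ``reaction`` elements (metabolic) are ignored: these are
signalling and cancer maps, not metabolism.

Only files supplied by the user are parsed; nothing is downloaded.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .core import RegulatoryNetwork, build_network

_SIGNED_SUBTYPES = {
    "activation": 1,
    "expression": 1,
    "inhibition": -1,
    "repression": -1,
}
_PTM_SUBTYPES = {
    "phosphorylation", "dephosphorylation", "ubiquitination",
    "glycosylation", "methylation",
}
# recognised subtypes that carry no sign of their own
_NEUTRAL_SUBTYPES = {
    "compound", "binding/association", "dissociation", "indirect effect",
    "state change", "missing interaction", "hidden compound",
} | _PTM_SUBTYPES

_ENTRY_KINDS = {
    "gene": "gene",
    "ortholog": "gene",
    "enzyme": "gene",
    "compound": "compound",
    "group": "group",
    "map": "map",
}


@dataclass
class KgmlEntry:
    """One KGML ``entry``: internal id, kind, display labels, and member
    entry ids for groups."""

    entry_id: str
    kind: str
    labels: list[str]
    members: list[str]


def _entry_labels(elem: ET.Element) -> list[str]:
    graphics = elem.find("graphics")
    raw = None
    if graphics is not None:
        raw = graphics.get("name")
    if not raw:
        raw = elem.get("name", "")
    labels = [tok.strip().rstrip(".") for tok in raw.replace(",", " ").split()]
    return [lab for lab in labels if lab and ":" not in lab] or \
           [lab for lab in labels if lab]


def _parse_entries(root: ET.Element) -> dict[str, KgmlEntry]:
    entries: dict[str, KgmlEntry] = {}
    for elem in root.findall("entry"):
        kind = _ENTRY_KINDS.get(elem.get("type", ""), "other")
        members = [c.get("id") for c in elem.findall("component")]
        entries[elem.get("id")] = KgmlEntry(
            entry_id=elem.get("id"),
            kind=kind,
            labels=_entry_labels(elem),
            members=[m for m in members if m],
        )
    return entries


def _relation_semantics(rel: ET.Element, warnings: list[str]):
    """Map a relation's type + subtypes to (sign, class, mechanism)."""
    rel_type = rel.get("type", "other")
    cls = rel_type if rel_type in ("PPrel", "GErel", "PCrel") else "other"
    sign = 0
    mechanisms: list[str] = []
    subtypes = rel.findall("subtype")
    if not subtypes:
        warnings.append(
            f"relation {rel.get('entry1')}->{rel.get('entry2')} "
            "has no subtype; kept with sign 0")
    for st in subtypes:
        name = (st.get("name") or "").strip()
        if name in _SIGNED_SUBTYPES:
            sign = _SIGNED_SUBTYPES[name]
            if name in ("expression", "repression"):
                cls = "GErel"
        elif name in _PTM_SUBTYPES:
            mechanisms.append(name)
            cls = "PTM"
        elif name == "compound":
            mechanisms.append(f"compound:{st.get('value', '')}")
            cls = "PCrel"
        elif name in _NEUTRAL_SUBTYPES:
            mechanisms.append(name)
        else:
            warnings.append(f"unknown relation subtype {name!r}; kept with sign 0")
            mechanisms.append(name)
    return sign, cls, (";".join(mechanisms) or None)


def parse_kgml(source, name: str | None = None,
               category: str = "other") -> RegulatoryNetwork:
    """Parse one KGML document (path, file object or XML string).

    Node ids are the first display label of each entry; remaining labels
    are kept as aliases.  Group entries are expanded (each member
    inherits the group's relations) and map/other entries dropped;
    relations referencing dropped or unknown entries are skipped with a
    warning."""
    if isinstance(source, (str, Path)) and not str(source).lstrip().startswith("<"):
        tree = ET.parse(source)
        root = tree.getroot()
    else:
        root = ET.fromstring(source if isinstance(source, str) else source.read())
    if root.tag != "pathway":
        raise ValueError(f"expected a <pathway> root, got <{root.tag}>")

    entries = _parse_entries(root)
    warnings: list[str] = []

    def resolve(entry_id: str) -> list[KgmlEntry]:
        """Terminal (gene/compound) entries an id stands for."""
        entry = entries.get(entry_id)
        if entry is None:
            return []
        if entry.kind == "group":
            out = []
            for m in entry.members:
                out.extend(resolve(m))
            return out
        if entry.kind in ("gene", "compound"):
            return [entry] if entry.labels else []
        return []  # map / other dropped

    net_name = name or root.get("title") or root.get("name") or "pathway"
    net = build_network(net_name, category=category)
    net.warnings.extend(warnings)

    for entry in entries.values():
        if entry.kind in ("gene", "compound") and entry.labels:
            net.add_node(entry.labels[0], kind=entry.kind,
                         aliases=entry.labels[1:])

    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        sources, targets = resolve(e1), resolve(e2)
        if not sources or not targets:
            net.warnings.append(
                f"relation {e1}->{e2} references unknown or dropped "
                "entries; skipped")
            continue
        sign, cls, mech = _relation_semantics(rel, net.warnings)
        for s_entry in sources:
            for t_entry in targets:
                net.add_edge(s_entry.labels[0], t_entry.labels[0],
                             sign, cls, mech)
    return net


def load_collection(directory,
                    manifest: Sequence[tuple[str, str]],
                    ) -> list[RegulatoryNetwork]:
    """Parse one network per manifest row ``(file, category)``.

    Files ending in ``.xml``/``.kgml`` are parsed as KGML, anything else
    as the signed edge-list TSV.  A missing file raises naming it."""
    from .core import read_edgelist

    directory = Path(directory)
    networks = []
    for filename, cat in manifest:
        path = directory / filename
        if not path.exists():
            raise FileNotFoundError(f"network file not found: {path}")
        if path.suffix.lower() in (".xml", ".kgml"):
            net = parse_kgml(path, name=path.stem, category=cat)
        else:
            net = read_edgelist(path, category=cat)
        networks.append(net)
    return networks
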