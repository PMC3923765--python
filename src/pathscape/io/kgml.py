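"""KGML (KEGG pathway XML) reader.

KGML carries node positions (entry graphics: x, y, width, height in map
pixels, top-left origin, y growing downward) but no edge routes — those are
the layouter's job.  Entries become entities (enzymes, compounds, linked
pathways), reaction elements become hyperedges, relation elements become
binary edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from lxml import etree

from ..errors import FormatError
from ..model import (
    Edge, Entity, Kind, NetworkModel, ReactionHyperedge, Relation,
)

logger = logging.getLogger(__name__)

_ENTRY_KINDS = {
    "enzyme": Kind.PROTEIN,
    "gene": Kind.GENE,
    "ortholog": Kind.PROTEIN,
    "compound": Kind.COMPOUND,
    "map": Kind.PATHWAY,
    "group": Kind.COMPLEX,
}

_RELATION_SUBTYPES = {
    "activation": Relation.ACTIVATION,
    "inhibition": Relation.INHIBITION,
    "phosphorylation": Relation.PHOSPHORYLATION,
    "binding/association": Relation.BINDING,
}


@dataclass
class KgmlLayoutHints:
    """Entry id -> (x, y, width, height) in KGML pixel coordinates."""

    positions: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nid, (x, y, w, h) in self.positions.items():
            if x < 0 or y < 0 or w < 0 or h < 0:
                raise FormatError(f"negative KGML coordinate for entry {nid!r}")

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.positions

    def __len__(self) -> int:
        return len(self.positions)


def read_kgml(xml: str | bytes) -> tuple[NetworkModel, KgmlLayoutHints]:
    """Parse KGML into a model plus verbatim layout hints.

    Hints are keyed by entry id; entries without a graphics element get no
    hint and fall back to computed placement.  All KEGG names of an entry are
    attached as xrefs of one entity.
    """
    if isinstance(xml, str):
        xml = xml.encode()
    try:
        root = etree.fromstring(xml)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed KGML: {exc}") from exc
    if root.tag != "pathway":
        raise FormatError(f"not a KGML document (root <{root.tag}>)")

    model = NetworkModel(name=root.get("name", "kgml"))
    hints: dict[str, tuple[float, float, float, float]] = {}

    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type", "enzyme")
        kind = _ENTRY_KINDS.get(etype, Kind.PROTEIN)
        names = (entry.get("name") or "").split()
        gfx = entry.find("graphics")
        label = eid
        if gfx is not None and gfx.get("name"):
            label = gfx.get("name").split(",")[0].strip()
        elif names:
            label = names[0]
        ent = Entity(eid, kind=kind, label=label,
                     xrefs={("kegg", n) for n in names})
        model.add_entity(ent)
        if gfx is not None and gfx.get("x") is not None and gfx.get("y") is not None:
            hints[eid] = (
                float(gfx.get("x")), float(gfx.get("y")),
                float(gfx.get("width", 46)), float(gfx.get("height", 17)),
            )

    for rxn in root.findall("reaction"):
        rid = rxn.get("id") or rxn.get("name", model.fresh_id("rxn"))
        subs = [(s.get("id") or s.get("name"), 1.0) for s in rxn.findall("substrate")]
        prods = [(p.get("id") or p.get("name"), 1.0) for p in rxn.findall("product")]
        # the enzyme entries whose reaction attribute names this reaction
        enzymes = [
            e.get("id") for e in root.findall("entry")
            if rxn.get("name") and rxn.get("name") in (e.get("reaction") or "").split()
        ]
        subs = [(s, c) for s, c in subs if s in model.entities]
        prods = [(p, c) for p, c in prods if p in model.entities]
        if not subs or not prods:
            logger.warning("KGML reaction %s: missing participants, skipped", rid)
            continue
        model.add_reaction(ReactionHyperedge(
            id=rid, substrates=subs, products=prods,
            catalysts=[e for e in enzymes if e in model.entities],
            reversible=rxn.get("type") == "reversible",
            label=rxn.get("name", rid),
        ))

    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 not in model.entities or e2 not in model.entities:
            continue
        relation = Relation.GENERIC
        for sub in rel.findall("subtype"):
            if sub.get("name") in _RELATION_SUBTYPES:
                relation = _RELATION_SUBTYPES[sub.get("name")]
                break
        model.add_edge(Edge(model.fresh_id("rel"), e1, e2, relation=relation))

    model.clear_dirty()
    return model, KgmlLayoutHints(hints)
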