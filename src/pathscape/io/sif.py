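"""SIF (simple interaction format) reader, Cytoscape dialect.

One interaction per line: ``source <ws> relation <ws> target [target ...]``.
The delimiter is tab whenever a tab occurs on the line, otherwise runs of
spaces; multi-target lines expand pairwise.  How each relation-type string is
translated into the model is configurable: plain edges of a given relation,
complex membership (builds a group), reaction co-factor flagging, or ignore.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from ..errors import FormatError
from ..model import Edge, Entity, Group, GroupSemantics, Kind, NetworkModel, Relation
from .idmap import IdMappingTable

logger = logging.getLogger(__name__)

EDGE_ACTIONS = {
    "edge(activation)": Relation.ACTIVATION,
    "edge(inhibition)": Relation.INHIBITION,
    "edge(phosphorylation)": Relation.PHOSPHORYLATION,
    "edge(binding)": Relation.BINDING,
    "edge(generic)": Relation.GENERIC,
}
ACTIONS = set(EDGE_ACTIONS) | {"complex_membership", "reaction_cofactor", "ignore"}


@dataclass
class SifTranslationConfig:
    """Relation-type string -> translation action.

    Actions: ``edge(<relation>)``, ``complex_membership``,
    ``reaction_cofactor``, ``ignore``.  Unmapped relation types fall back to
    ``default_action``.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    default_action: str = "edge(generic)"

    def __post_init__(self) -> None:
        for rel, action in {**self.mapping, "_": self.default_action}.items():
            if action not in ACTIONS:
                raise FormatError(f"unknown SIF action {action!r} for {rel!r}")

    def action_for(self, relation_type: str) -> str:
        return self.mapping.get(relation_type, self.default_action)


#: Reasonable defaults covering common Cytoscape relation strings.
DEFAULT_SIF_CONFIG = SifTranslationConfig(
    mapping={
        "activation": "edge(activation)",
        "activates": "edge(activation)",
        "inhibition": "edge(inhibition)",
        "inhibits": "edge(inhibition)",
        "phosphorylation": "edge(phosphorylation)",
        "phosphorylates": "edge(phosphorylation)",
        "pp": "edge(binding)",
        "binding": "edge(binding)",
        "complex": "complex_membership",
        "component_of": "complex_membership",
        "cofactor": "reaction_cofactor",
    }
)


def _tokenize(line: str) -> list[str]:
    if "\t" in line:
        return [t.strip() for t in line.split("\t") if t.strip()]
    return [t for t in re.split(r" +", line.strip()) if t]


def read_sif(
    text: str,
    config: Optional[SifTranslationConfig] = None,
    mapping: Optional[IdMappingTable] = None,
) -> NetworkModel:
    """Parse SIF text into a model.

    Entities are created on first mention (kind ``protein``; a mapping table,
    when given, rewrites identifiers and keeps the original as an xref).
    Duplicate identical interactions collapse to a single edge.  Lines with a
    single token create isolated entities, two-token lines are skipped with a
    warning.
    """
    config = config or DEFAULT_SIF_CONFIG
    model = NetworkModel(name="sif")
    seen_edges: set[tuple[str, str, Relation]] = set()
    complexes: dict[str, str] = {}  # source id -> group id
    cofactor_groups: dict[str, str] = {}
    n_edges = 0

    def intern(raw: str) -> str:
        eid = mapping.map_one(raw) if mapping else raw
        if eid not in model.entities:
            ent = Entity(eid, kind=Kind.PROTEIN)
            if mapping and eid != raw:
                ent.xrefs.add(("source", raw))
            model.add_entity(ent)
        return eid

    deferred_groups: list[tuple[str, str, GroupSemantics]] = []

    for ln, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        tokens = _tokenize(line)
        if len(tokens) == 1:
            intern(tokens[0])
            continue
        if len(tokens) == 2:
            logger.warning("SIF line %d: %d tokens, skipped", ln, len(tokens))
            continue
        src_raw, rel = tokens[0], tokens[1]
        action = config.action_for(rel)
        if action == "ignore":
            continue
        src = intern(src_raw)
        for tgt_raw in tokens[2:]:
            tgt = intern(tgt_raw)
            if action in EDGE_ACTIONS:
                key = (src, tgt, EDGE_ACTIONS[action])
                if key in seen_edges:
                    continue
                seen_edges.add(key)
                model.add_edge(Edge(model.fresh_id("e"), src, tgt,
                                    relation=EDGE_ACTIONS[action]))
                n_edges += 1
            elif action == "complex_membership":
                deferred_groups.append((src, tgt, GroupSemantics.COMPLEX))
            elif action == "reaction_cofactor":
                deferred_groups.append((src, tgt, GroupSemantics.REACTION_COFACTORS))

    # groups are built last so a member mentioned on several lines lands in
    # exactly one group keyed by the line's source identifier
    for src, tgt, semantics in deferred_groups:
        table = complexes if semantics is GroupSemantics.COMPLEX else cofactor_groups
        gid = table.get(src)
        if gid is None:
            gid = f"{'complex' if semantics is GroupSemantics.COMPLEX else 'cofactors'}:{src}"
            table[src] = gid
            members = [src, tgt] if semantics is GroupSemantics.COMPLEX else [tgt]
            members = list(dict.fromkeys(m for m in members if m not in model.parent))
            if not members:
                del table[src]
                continue
            model.add_group(Group(gid, member_ids=members, semantics=semantics))
        else:
            g = model.groups[gid]
            if tgt not in g.member_ids and tgt not in model.parent:
                g.member_ids.append(tgt)
                model.parent[tgt] = gid

    logger.info("SIF: %d entities, %d edges", len(model.entities), n_edges)
    model.clear_dirty()
    return model
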