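"""Hierarchical network model.

The model is a compound graph: plain entities (proteins, genes, compounds, ...)
can be nested inside groups (complexes, families, pathways, reaction co-factor
satellites), reactions are hyperedges joining substrates, products and
catalysts, and binary edges carry regulatory relation types.  Groups collapse
to a single node for rendering; entities can be *aliased* — drawn as several
instances in different contexts — and merged back.

Graphical appearance is resolved through four stacked property layers
(``default < style < user_override < projection``): a query for any
(component, property) pair always yields a value, falling through to the
built-in defaults.

Mutating operations mark components *dirty* (topological / visual / layout)
so a renderer can update incrementally; a completed render clears the flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any, Iterable, Optional

from .errors import ConfigError, NotFoundError

logger = logging.getLogger(__name__)


class Kind(str, Enum):
    PROTEIN = "protein"
    GENE = "gene"
    RNA = "rna"
    COMPOUND = "compound"
    COMPLEX = "complex"
    FAMILY = "family"
    PATHWAY = "pathway"


class GroupSemantics(str, Enum):
    COMPLEX = "complex"
    FAMILY = "family"
    PATHWAY = "pathway"
    REACTION_COFACTORS = "reaction_cofactors"
    GENERIC = "generic"
    STAR = "star"


class Relation(str, Enum):
    ACTIVATION = "activation"
    INHIBITION = "inhibition"
    PHOSPHORYLATION = "phosphorylation"
    BINDING = "binding"
    GENERIC = "generic"


class Scope(str, Enum):
    """Property layers in ascending priority."""

    DEFAULT = "default"
    STYLE = "style"
    USER_OVERRIDE = "user_override"
    PROJECTION = "projection"


SCOPE_ORDER = [Scope.DEFAULT, Scope.STYLE, Scope.USER_OVERRIDE, Scope.PROJECTION]

#: Canonical graphical properties plus ``direction`` (used by the
#: reaction-direction projection target; defaults to "forward").
PROPERTY_DEFAULTS: dict[str, Any] = {
    "label": "",
    "shape": "ellipse",
    "size": (48.0, 28.0),
    "fill_color": "#FFFFFF",
    "stroke_color": "#000000",
    "line_width": 1.0,
    "font": "sans-serif 11",
    "visible": True,
    "direction": "forward",
}

#: Shape defaults by entity kind, below any explicit layer assignment.
KIND_SHAPES: dict[Kind, str] = {
    Kind.PROTEIN: "rounded_rect",
    Kind.GENE: "rect",
    Kind.RNA: "parallelogram",
    Kind.COMPOUND: "circle",
    Kind.COMPLEX: "octagon",
    Kind.FAMILY: "rect",
    Kind.PATHWAY: "rect",
}


class Dirty(str, Enum):
    TOPOLOGICAL = "topological"
    VISUAL = "visual"
    LAYOUT = "layout"


@dataclass
class Entity:
    id: str
    kind: Kind = Kind.PROTEIN
    label: str = ""
    xrefs: set[tuple[str, str]] = field(default_factory=set)
    compartments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kind = Kind(self.kind)
        if not self.label:
            self.label = self.id


@dataclass
class Group:
    id: str
    member_ids: list[str]
    semantics: GroupSemantics = GroupSemantics.GENERIC
    collapsed: bool = False
    own_layout: Optional[str] = None
    #: only for star groups: the member the others attach to radially
    hub_id: Optional[str] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.semantics = GroupSemantics(self.semantics)
        if not self.member_ids:
            raise ConfigError(f"group {self.id!r} has no members")
        if not self.label:
            self.label = self.id


@dataclass
class ReactionHyperedge:
    """A biochemical reaction: substrates -> products, catalysed by enzymes.

    Co-factors are participants (already present among substrates/products)
    flagged for satellite placement or hiding — ATP/ADP-style currency
    metabolites that would otherwise clutter the drawing.
    """

    id: str
    substrates: list[tuple[str, float]]
    products: list[tuple[str, float]]
    catalysts: list[str] = field(default_factory=list)
    cofactors: list[str] = field(default_factory=list)
    reversible: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ConfigError(f"reaction {self.id!r} needs substrates and products")
        participants = {e for e, _ in self.substrates} | {e for e, _ in self.products}
        bad = set(self.cofactors) - participants
        if bad:
            raise ConfigError(
                f"reaction {self.id!r}: co-factors {sorted(bad)} are not participants"
            )
        if not self.label:
            self.label = self.id

    @property
    def participant_ids(self) -> set[str]:
        return {e for e, _ in self.substrates} | {e for e, _ in self.products}


@dataclass
class Edge:
    id: str
    source: str
    target: str
    relation: Relation = Relation.GENERIC
    directed: bool = True
    multiplicity: int = 1

    def __post_init__(self) -> None:
        self.relation = Relation(self.relation)


@dataclass
class AliasInstance:
    """One visual instance of an entity inside a context (group/pathway)."""

    id: str
    entity_id: str
    context_id: Optional[str] = None


@dataclass
class PropertyLayer:
    scope: Scope
    assignments: dict[str, dict[str, Any]] = field(default_factory=dict)

    def set(self, component_id: str, prop: str, value: Any) -> None:
        if prop not in PROPERTY_DEFAULTS:
            raise ConfigError(f"unknown property {prop!r}")
        self.assignments.setdefault(component_id, {})[prop] = value

    def get(self, component_id: str, prop: str) -> Any:
        return self.assignments.get(component_id, {}).get(prop)


class NetworkModel:
    """Container for all components plus hierarchy, layers and dirty state."""

    def __init__(self, name: str = "model") -> None:
        self.name = name
        self.entities: dict[str, Entity] = {}
        self.groups: dict[str, Group] = {}
        self.reactions: dict[str, ReactionHyperedge] = {}
        self.edges: dict[str, Edge] = {}
        self.aliases: dict[str, AliasInstance] = {}
        #: child component id -> parent group id
        self.parent: dict[str, str] = {}
        self.layers: dict[Scope, PropertyLayer] = {
            s: PropertyLayer(s) for s in SCOPE_ORDER
        }
        self.dirty: dict[str, set[Dirty]] = {}
        #: bumped on every topological mutation; used for flat-graph staleness
        self.topology_revision = 0
        self._id_counter = 0

    # -- id & lookup helpers ------------------------------------------------

    def fresh_id(self, prefix: str = "ps") -> str:
        self._id_counter += 1
        return f"{prefix}{self._id_counter:06d}"

    def has(self, component_id: str) -> bool:
        return (
            component_id in self.entities
            or component_id in self.groups
            or component_id in self.reactions
            or component_id in self.edges
            or component_id in self.aliases
        )

    def component(self, component_id: str) -> Any:
        for table in (self.entities, self.groups, self.reactions, self.aliases, self.edges):
            if component_id in table:
                return table[component_id]
        raise NotFoundError(component_id)

    def node_component_ids(self) -> list[str]:
        """All node-like component ids (entities, groups, reactions, aliases)."""
        return (
            list(self.entities) + list(self.groups)
            + list(self.reactions) + list(self.aliases)
        )

    # -- construction -------------------------------------------------------

    def add_entity(self, entity: Entity) -> Entity:
        if self.has(entity.id):
            raise ConfigError(f"duplicate component id {entity.id!r}")
        self.entities[entity.id] = entity
        self._touch(entity.id, Dirty.TOPOLOGICAL)
        return entity

    def add_group(self, group: Group) -> Group:
        if self.has(group.id):
            raise ConfigError(f"duplicate component id {group.id!r}")
        for m in group.member_ids:
            if not self.has(m):
                raise NotFoundError(m)
            if m in self.parent:
                raise ConfigError(f"component {m!r} already has a parent")
        self.groups[group.id] = group
        for m in group.member_ids:
            self.parent[m] = group.id
        self._check_acyclic(group.id)
        self._touch(group.id, Dirty.TOPOLOGICAL)
        return group

    def add_star(self, group_id: str, hub_id: str, satellite_ids: list[str]) -> Group:
        """A star: a degenerate group whose satellites attach radially to a hub.

        The hub and satellites become members; rendering connects each
        satellite to the hub and lays them out on a circle.
        """
        g = Group(
            id=group_id,
            member_ids=[hub_id] + list(satellite_ids),
            semantics=GroupSemantics.STAR,
            hub_id=hub_id,
        )
        return self.add_group(g)

    def add_reaction(self, rxn: ReactionHyperedge) -> ReactionHyperedge:
        if self.has(rxn.id):
            raise ConfigError(f"duplicate component id {rxn.id!r}")
        for pid in rxn.participant_ids | set(rxn.catalysts):
            if not self.has(pid):
                raise NotFoundError(pid)
        self.reactions[rxn.id] = rxn
        self._touch(rxn.id, Dirty.TOPOLOGICAL)
        return rxn

    def add_edge(self, edge: Edge) -> Edge:
        if self.has(edge.id):
            raise ConfigError(f"duplicate component id {edge.id!r}")
        for ref in (edge.source, edge.target):
            if not self.has(ref):
                raise NotFoundError(ref)
        self.edges[edge.id] = edge
        self._touch(edge.id, Dirty.TOPOLOGICAL)
        return edge

    def _check_acyclic(self, start: str) -> None:
        seen = set()
        cur: Optional[str] = start
        while cur is not None:
            if cur in seen:
                raise ConfigError(f"hierarchy cycle through {start!r}")
            seen.add(cur)
            cur = self.parent.get(cur)

    def _touch(self, component_id: str, kind: Dirty) -> None:
        self.dirty.setdefault(component_id, set()).add(kind)
        if kind is Dirty.TOPOLOGICAL:
            self.topology_revision += 1

    def clear_dirty(self) -> None:
        self.dirty.clear()

    # -- collapse / expand --------------------------------------------------

    def collapse_group(self, group_id: str) -> "NetworkModel":
        """Collapse a group to a single rendered node.

        Member components disappear from the drawing; their external edges are
        re-attached to the group node, and parallel re-attached edges merge
        into one aggregate edge carrying a multiplicity count (done at render
        time — the model's own edges are untouched, so expanding restores the
        original topology exactly).  Collapsing an already-collapsed group is
        a no-op.
        """
        g = self.groups.get(group_id)
        if g is None:
            raise NotFoundError(group_id)
        if g.collapsed:
            return self
        g.collapsed = True
        self._touch(group_id, Dirty.TOPOLOGICAL)
        return self

    def expand_group(self, group_id: str) -> "NetworkModel":
        g = self.groups.get(group_id)
        if g is None:
            raise NotFoundError(group_id)
        if not g.collapsed:
            return self
        g.collapsed = False
        self._touch(group_id, Dirty.TOPOLOGICAL)
        return self

    # -- aliasing -----------------------------------------------------------

    def create_alias(self, entity_id: str, context_id: Optional[str] = None) -> str:
        """Add a visual instance of *entity_id* in the given context."""
        if entity_id not in self.entities:
            raise NotFoundError(entity_id)
        if context_id is not None and not self.has(context_id):
            raise NotFoundError(context_id)
        iid = self.fresh_id("alias")
        self.aliases[iid] = AliasInstance(iid, entity_id, context_id)
        if context_id in self.groups:
            self.groups[context_id].member_ids.append(iid)
            self.parent[iid] = context_id
        self._touch(entity_id, Dirty.TOPOLOGICAL)
        return iid

    def instances_of(self, entity_id: str) -> list[str]:
        return sorted(i for i, a in self.aliases.items() if a.entity_id == entity_id)

    def highlight_instances(self, entity_id: str) -> list[str]:
        """All instance ids of an entity (for cross-context highlighting)."""
        return self.instances_of(entity_id)

    def merge_aliases(self, entity_id: str) -> "NetworkModel":
        """Merge all instances of an entity back into one.

        Edges of the removed instances re-attach to the survivor; duplicates
        collapse into one edge with summed multiplicity.  An entity with a
        single instance (or none) is left unchanged.
        """
        inst = self.instances_of(entity_id)
        if len(inst) < 2:
            return self
        keep, drop = inst[0], inst[1:]
        dropped = set(drop)
        for iid in drop:
            a = self.aliases.pop(iid)
            ctx = self.parent.pop(iid, None)
            if ctx in self.groups:
                g = self.groups[ctx]
                g.member_ids = [m for m in g.member_ids if m != iid]
                if not g.member_ids:  # groups must stay non-empty
                    del self.groups[ctx]
                    self.parent.pop(ctx, None)
            del a
        # re-attach and deduplicate edges
        seen: dict[tuple, str] = {}
        for eid in sorted(self.edges):
            e = self.edges[eid]
            if e.source in dropped:
                e.source = keep
            if e.target in dropped:
                e.target = keep
            key = (e.source, e.target, e.relation, e.directed)
            if key in seen:
                self.edges[seen[key]].multiplicity += e.multiplicity
                del self.edges[eid]
            else:
                seen[key] = eid
        self._touch(entity_id, Dirty.TOPOLOGICAL)
        return self

    # -- neighborhood expansion --------------------------------------------

    def expand_neighborhood(
        self, entity_id: str, direction: str, source: "NetworkModel"
    ) -> "NetworkModel":
        """Pull an entity's neighborhood from a reference network.

        ``direction`` is ``upstream`` (in-edges), ``downstream`` (out-edges)
        or ``both``.  Endpoint entities and the connecting edges are copied in;
        components already present are never duplicated, so the operation is
        idempotent.
        """
        if direction not in ("upstream", "downstream", "both"):
            raise ConfigError(f"bad direction {direction!r}")
        if entity_id not in self.entities:
            raise NotFoundError(entity_id)
        if entity_id not in source.entities:
            logger.warning("entity %s absent from source network; nothing to expand",
                           entity_id)
            return self
        for eid in sorted(source.edges):
            e = source.edges[eid]
            incoming = e.target == entity_id
            outgoing = e.source == entity_id
            if not (incoming or outgoing):
                continue
            if direction == "upstream" and not (incoming or (not e.directed and outgoing)):
                continue
            if direction == "downstream" and not (outgoing or (not e.directed and incoming)):
                continue
            other = e.source if incoming else e.target
            if other not in self.entities and other in source.entities:
                src_ent = source.entities[other]
                self.add_entity(replace(
                    src_ent,
                    xrefs=set(src_ent.xrefs),
                    compartments=list(src_ent.compartments),
                ))
            if eid not in self.edges and self.has(e.source) and self.has(e.target):
                self.add_edge(replace(e))
        return self

    # -- property resolution ------------------------------------------------

    def set_property(self, component_id: str, prop: str, value: Any,
                     scope: Scope = Scope.USER_OVERRIDE) -> None:
        if not self.has(component_id):
            raise NotFoundError(component_id)
        self.layers[scope].set(component_id, prop, value)
        self._touch(component_id, Dirty.VISUAL if prop != "visible" else Dirty.TOPOLOGICAL)

    def clear_projection_layer(self) -> None:
        """Drop all projected assignments, restoring the prior appearance."""
        had_visibility = any(
            "visible" in props
            for props in self.layers[Scope.PROJECTION].assignments.values()
        )
        for cid in self.layers[Scope.PROJECTION].assignments:
            self._touch(cid, Dirty.TOPOLOGICAL if had_visibility else Dirty.VISUAL)
        self.layers[Scope.PROJECTION] = PropertyLayer(Scope.PROJECTION)

    def resolve_property(self, component_id: str, prop: str) -> Any:
        """Value from the highest-priority layer assigning it, else default."""
        if prop not in PROPERTY_DEFAULTS:
            raise ConfigError(f"unknown property {prop!r}")
        if not self.has(component_id):
            raise NotFoundError(component_id)
        for scope in reversed(SCOPE_ORDER):
            v = self.layers[scope].get(component_id, prop)
            if v is not None:
                return v
        if prop == "label":
            comp = self.component(component_id)
            return getattr(comp, "label", component_id)
        if prop == "shape":
            comp = self.component(component_id)
            if isinstance(comp, Entity):
                return KIND_SHAPES[comp.kind]
            if isinstance(comp, AliasInstance):
                return KIND_SHAPES[self.entities[comp.entity_id].kind]
            if isinstance(comp, ReactionHyperedge):
                return "small_circle"
            if isinstance(comp, Group):
                return "rect"
        return PROPERTY_DEFAULTS[prop]

    def apply_style(self, style: dict[str, dict[str, Any]]) -> None:
        """Install a visual style: property bundles keyed by entity kind
        (or ``reaction``/``group``/``edge``), expanded into the style layer."""
        layer = PropertyLayer(Scope.STYLE)
        for cid in self.entities:
            bundle = style.get(self.entities[cid].kind.value)
            if bundle:
                for p, v in bundle.items():
                    layer.set(cid, p, v)
        for iid, a in self.aliases.items():
            bundle = style.get(self.entities[a.entity_id].kind.value)
            if bundle:
                for p, v in bundle.items():
                    layer.set(iid, p, v)
        for table, key in ((self.reactions, "reaction"), (self.groups, "group"),
                           (self.edges, "edge")):
            bundle = style.get(key)
            if bundle:
                for cid in table:
                    for p, v in bundle.items():
                        layer.set(cid, p, v)
        self.layers[Scope.STYLE] = layer
        for cid in self.node_component_ids():
            self._touch(cid, Dirty.VISUAL)

    # -- misc ---------------------------------------------------------------

    def leaf_entity_ids(self) -> set[str]:
        return set(self.entities)

    def children_of(self, group_id: str) -> list[str]:
        return list(self.groups[group_id].member_ids)

    def ancestors_of(self, component_id: str) -> Iterable[str]:
        cur = self.parent.get(component_id)
        while cur is not None:
            yield cur
            cur = self.parent.get(cur)

    def is_hidden_by_collapse(self, component_id: str) -> bool:
        """True when some ancestor group is collapsed."""
        return any(self.groups[a].collapsed
                   for a in self.ancestors_of(component_id) if a in self.groups)

    def collapse_root(self, component_id: str) -> Optional[str]:
        """The outermost collapsed ancestor group, if any."""
        root = None
        for a in self.ancestors_of(component_id):
            if a in self.groups and self.groups[a].collapsed:
                root = a
        return root
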