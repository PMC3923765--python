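"""Flattening the hierarchical model into a simple directed graph, path
algorithms on it, and back-projection of results as highlights.

Group nesting, reaction hyperedges and entity aliases make classical graph
algorithms ill-defined on the visualization model, so analyses run on a
*flattened* simple digraph.  How each construct flattens is configurable
(:class:`FlatteningPolicy`); origin maps record which model components every
flat node and edge came from, so results can be projected back onto the
drawing as node/edge colorings.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .errors import ConfigError, NotFoundError, StalenessError
from .model import GroupSemantics, NetworkModel, PropertyLayer, Scope


@dataclass(frozen=True)
class FlatteningPolicy:
    """All fields must be set explicitly — no implicit defaults at call sites.

    * ``family_mode``: ``split_into_members`` replaces a family node by its
      members, each inheriting every edge of the family; ``single_node``
      keeps one node standing for the whole family.
    * ``complex_mode``: ``single_node``, ``clique`` (pairwise binding edges
      between members, both directions) or ``star_to_members`` (complex node
      kept, one edge to each member).
    * ``reaction_mode``: ``bipartite`` keeps reaction nodes;
      ``substrate_to_product_edges`` contracts each reaction to one edge per
      (substrate, product) pair.
    * ``alias_mode``: ``merge_instances`` or ``keep_instances``.
    * ``include_cofactors``: drop co-factor participation edges when false.
    """

    family_mode: str
    complex_mode: str
    reaction_mode: str
    alias_mode: str
    include_cofactors: bool

    _ALLOWED = {
        "family_mode": ("split_into_members", "single_node"),
        "complex_mode": ("single_node", "clique", "star_to_members"),
        "reaction_mode": ("bipartite", "substrate_to_product_edges"),
        "alias_mode": ("merge_instances", "keep_instances"),
    }

    def __post_init__(self) -> None:
        for fname, allowed in self._ALLOWED.items():
            if getattr(self, fname) not in allowed:
                raise ConfigError(
                    f"{fname} must be one of {allowed}, got {getattr(self, fname)!r}")


#: identity-ish policy useful for plain interaction networks
DEFAULT_POLICY = FlatteningPolicy(
    family_mode="split_into_members",
    complex_mode="single_node",
    reaction_mode="bipartite",
    alias_mode="merge_instances",
    include_cofactors=True,
)


@dataclass
class FlatGraph:
    graph: nx.DiGraph
    node_origin: dict[str, set[str]]
    edge_origin: dict[tuple[str, str], set[str]]
    model_revision: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def flatten(model: NetworkModel, policy: FlatteningPolicy) -> FlatGraph:
    """Flatten the model into a simple digraph with invertible origin maps.

    Parallel edges fold into one with summed ``weight``; a projection-bound
    weight hook may overwrite weights afterwards.  The result is independent
    of component insertion order.
    """
    g = nx.DiGraph()
    node_origin: dict[str, set[str]] = {}
    edge_origin: dict[tuple[str, str], set[str]] = {}

    def resolve(ref: str) -> list[str]:
        """Model component id -> flat node id(s) standing for it."""
        if ref in model.aliases:
            if policy.alias_mode == "merge_instances":
                return resolve(model.aliases[ref].entity_id)
            return [ref]
        if ref in model.groups:
            grp = model.groups[ref]
            if grp.semantics is GroupSemantics.FAMILY \
                    and policy.family_mode == "split_into_members":
                return [m for mem in grp.member_ids for m in resolve(mem)]
            if grp.semantics is GroupSemantics.COMPLEX \
                    and policy.complex_mode == "clique":
                return [m for mem in grp.member_ids for m in resolve(mem)]
            return [ref]
        if ref in model.entities:
            if policy.alias_mode == "keep_instances":
                inst = model.instances_of(ref)
                if inst:
                    return inst
            return [ref]
        return [ref] if model.has(ref) else []

    def add_node(fid: str, origins: Sequence[str]) -> None:
        if fid not in g:
            label = fid
            if model.has(fid):
                comp = model.component(fid)
                label = getattr(comp, "label", fid)
            g.add_node(fid, label=label)
            node_origin[fid] = set()
        node_origin[fid].update(origins)

    def add_edge(u: str, v: str, origins: Sequence[str],
                 relation: str = "generic", weight: float = 1.0) -> None:
        if u == v:
            return
        if g.has_edge(u, v):
            # simple graph: parallel edges fold into a multiplicity count;
            # path weights stay 1 per edge unless a weight hook overwrites them
            g[u][v]["multiplicity"] += 1
        else:
            g.add_edge(u, v, weight=weight, relation=relation, multiplicity=1)
        edge_origin.setdefault((u, v), set()).update(origins)

    # nodes: entities (or their instances), unexpanded groups, reactions
    for eid in sorted(model.entities):
        for fid in resolve(eid):
            add_node(fid, [eid, fid] if fid != eid else [eid])
    for gid in sorted(model.groups):
        grp = model.groups[gid]
        if grp.semantics is GroupSemantics.REACTION_COFACTORS:
            continue
        targets = resolve(gid)
        for fid in targets:
            origins = [gid] if fid == gid else [gid, fid]
            add_node(fid, origins)
        if grp.semantics is GroupSemantics.COMPLEX:
            members = [m for mem in grp.member_ids for m in resolve(mem)]
            if policy.complex_mode == "clique":
                for a, b in itertools.combinations(sorted(set(members)), 2):
                    add_edge(a, b, [gid], relation="binding")
                    add_edge(b, a, [gid], relation="binding")
            elif policy.complex_mode == "star_to_members":
                for m in sorted(set(members)):
                    add_node(m, [m])
                    add_edge(gid, m, [gid], relation="binding")

    if policy.reaction_mode == "bipartite":
        for rid in sorted(model.reactions):
            add_node(rid, [rid])

    # binary edges, expanded through the policy
    for eid in sorted(model.edges):
        e = model.edges[eid]
        for u in resolve(e.source):
            for v in resolve(e.target):
                add_edge(u, v, [eid], relation=e.relation.value)
                if not e.directed:
                    add_edge(v, u, [eid], relation=e.relation.value)

    # reactions
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        subs = [s for s, _ in rxn.substrates
                if policy.include_cofactors or s not in rxn.cofactors]
        prods = [p for p, _ in rxn.products
                 if policy.include_cofactors or p not in rxn.cofactors]
        if policy.reaction_mode == "bipartite":
            for s in sorted(subs):
                for u in resolve(s):
                    add_edge(u, rid, [rid])
                    if rxn.reversible:
                        add_edge(rid, u, [rid])
            for p in sorted(prods):
                for v in resolve(p):
                    add_edge(rid, v, [rid])
                    if rxn.reversible:
                        add_edge(v, rid, [rid])
            for c in sorted(rxn.catalysts):
                for u in resolve(c):
                    add_edge(u, rid, [rid], relation="catalysis")
        else:
            for s in sorted(subs):
                for p in sorted(prods):
                    for u in resolve(s):
                        for v in resolve(p):
                            add_edge(u, v, [rid], relation="reaction")
                            if rxn.reversible:
                                add_edge(v, u, [rid], relation="reaction")

    return FlatGraph(graph=g, node_origin=node_origin, edge_origin=edge_origin,
                     model_revision=model.topology_revision)


def bind_edge_weights(flat: FlatGraph, weights: dict[tuple[str, str], float]) -> None:
    """Hook: overwrite flat edge weights (e.g. from a projected sample)."""
    for (u, v), w in weights.items():
        if flat.graph.has_edge(u, v):
            flat.graph[u][v]["weight"] = float(w)


# -- path algorithms --------------------------------------------------------

def _path_key(g: nx.DiGraph, path: list[str]) -> tuple:
    weight = sum(g[u][v].get("weight", 1.0) for u, v in zip(path, path[1:]))
    return (weight, len(path) - 1, tuple(path))


def _best_path(g: nx.DiGraph, source: str, target: str,
               banned_nodes: set[str], banned_edges: set[tuple[str, str]]
               ) -> Optional[list[str]]:
    """Dijkstra with the full deterministic tie-break key on the heap."""
    heap = [(0.0, 0, (source,))]
    best_seen: dict[str, tuple] = {}
    while heap:
        dist, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node == target:
            return list(path)
        key = (dist, hops, path)
        if node in best_seen and best_seen[node] < key:
            continue
        for nbr in sorted(g.successors(node)):
            if nbr in banned_nodes or nbr in path:
                continue
            if (node, nbr) in banned_edges:
                continue
            w = g[node][nbr].get("weight", 1.0)
            new = (dist + w, hops + 1, path + (nbr,))
            if nbr not in best_seen or new < best_seen[nbr]:
                best_seen[nbr] = new
                heapq.heappush(heap, new)
    return None


def k_shortest_paths(flat: FlatGraph | nx.DiGraph, source: str, target: str,
                     k: int) -> list[list[str]]:
    """Yen's algorithm for the k shortest loopless paths.

    Paths are ordered by (total weight, hop count, lexicographic node
    sequence); fewer than *k* paths are returned when fewer exist, and an
    unreachable target yields an empty list.
    """
    g = flat.graph if isinstance(flat, FlatGraph) else flat
    if source == target:
        raise ConfigError("source and target must differ")
    if k < 1:
        raise ConfigError("k must be >= 1")
    for n in (source, target):
        if n not in g:
            raise NotFoundError(n)

    first = _best_path(g, source, target, set(), set())
    if first is None:
        return []
    paths = [first]
    candidates: list[tuple[tuple, list[str]]] = []
    seen_candidates: set[tuple[str, ...]] = {tuple(first)}

    while len(paths) < k:
        prev = paths[-1]
        for i in range(len(prev) - 1):
            spur_node = prev[i]
            root = prev[: i + 1]
            banned_edges = set()
            for p in paths:
                if len(p) > i and p[: i + 1] == root:
                    banned_edges.add((p[i], p[i + 1]))
            banned_nodes = set(root[:-1])
            spur = _best_path(g, spur_node, target, banned_nodes, banned_edges)
            if spur is None:
                continue
            total = root[:-1] + spur
            key = tuple(total)
            if key not in seen_candidates:
                seen_candidates.add(key)
                heapq.heappush(candidates, (_path_key(g, total), total))
        if not candidates:
            break
        _, best = heapq.heappop(candidates)
        paths.append(best)

    return sorted(paths, key=lambda p: _path_key(g, p))[:k]


def bfs_distances(flat: FlatGraph | nx.DiGraph, source: str,
                  undirected: bool = False) -> dict[str, int]:
    """Unweighted hop distances from *source*; unreachable nodes absent."""
    g = flat.graph if isinstance(flat, FlatGraph) else flat
    if source not in g:
        raise NotFoundError(source)
    if undirected:
        g = g.to_undirected(as_view=True)
    return dict(nx.single_source_shortest_path_length(g, source))


# -- back-projection --------------------------------------------------------

def backproject(
    model: NetworkModel,
    flat: FlatGraph,
    result: list[list[str]] | dict[str, int],
    highlight_color: str = "#FF8800",
    scale_colors: tuple[str, str] = ("#08306B", "#C6DBEF"),
) -> PropertyLayer:
    """Color the model components a flat result originated from.

    Path lists highlight every origin component of nodes and edges on the
    paths; distance maps color origins on a sequential scale from the darkest
    (distance 0) to the lightest shade.  Raises
    :class:`~pathscape.errors.StalenessError` when the model's topology
    changed after flattening.
    """
    if flat.model_revision != model.topology_revision:
        raise StalenessError(
            "model topology changed since flatten(); re-flatten before "
            "back-projecting")
    layer = PropertyLayer(Scope.PROJECTION)

    def paint(component_ids: set[str], color: str) -> None:
        for cid in sorted(component_ids):
            if not model.has(cid):
                continue
            if cid in model.edges:
                layer.set(cid, "stroke_color", color)
            else:
                layer.set(cid, "fill_color", color)
                layer.set(cid, "stroke_color", color)

    if isinstance(result, dict):
        if result:
            dmax = max(result.values()) or 1
            from .projection import ColorScale
            scale = ColorScale(domain=(0.0, dmax / 2, float(dmax)),
                               range=(scale_colors[0],
                                      _mid_hex(scale_colors[0], scale_colors[1]),
                                      scale_colors[1]))
            for node, dist in sorted(result.items()):
                paint(flat.node_origin.get(node, set()), scale(float(dist)))
    else:
        for path in result:
            for node in path:
                paint(flat.node_origin.get(node, set()), highlight_color)
            for u, v in zip(path, path[1:]):
                paint(flat.edge_origin.get((u, v), set()), highlight_color)

    model.layers[Scope.PROJECTION] = layer
    from .model import Dirty
    for cid in layer.assignments:
        model._touch(cid, Dirty.VISUAL)
    return layer


def _mid_hex(a: str, b: str) -> str:
    av = [int(a[i:i + 2], 16) for i in (1, 3, 5)]
    bv = [int(b[i:i + 2], 16) for i in (1, 3, 5)]
    return "#%02X%02X%02X" % tuple((x + y) // 2 for x, y in zip(av, bv))
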