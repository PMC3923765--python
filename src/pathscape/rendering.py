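"""Three-step rendering pipeline with incremental updates, and SVG output.

Rendering turns the hierarchical model into a flat drawable graph in three
steps: (1) topology construction — collapsed groups become single nodes with
aggregate edges, reactions expand into bipartite stars, hidden components are
dropped; (2) attribute assignment — every drawable element gets a fully
resolved property set through the model's layer stack; (3) layout — one of
the engines positions nodes and routes edges.

Model mutations mark components dirty as topological, visual or layout
changes; :func:`incremental_update` re-runs only the steps a change kind
requires, and its defining contract is equality with a from-scratch render.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

from .errors import ConfigError, StateError
from .layouts import (
    CompartmentModel, LayoutResult, assign_layers, layout_force, layout_kegg,
    layout_layered,
)
from .model import Dirty, GroupSemantics, NetworkModel, Relation
from .projection import GlyphSpec

RESOLVED_PROPS = ("label", "shape", "size", "fill_color", "stroke_color",
                  "line_width", "font", "visible")

GLYPH_BOX = (48.0, 32.0)


@dataclass
class RenderNode:
    id: str
    origin: str
    kind: str  # entity | alias | group | reaction
    props: dict[str, Any] = field(default_factory=dict)
    geometry: Optional[tuple[float, float, float, float]] = None
    glyph: Optional[GlyphSpec] = None


@dataclass
class RenderEdge:
    id: str
    origins: tuple[str, ...]
    source: str
    target: str
    relation: str = "generic"
    directed: bool = True
    multiplicity: int = 1
    kind: str = "edge"  # edge | aggregate | reaction_sub | reaction_prod | catalysis | star
    props: dict[str, Any] = field(default_factory=dict)
    route: Optional[tuple[str, list[tuple[float, float]]]] = None


class RenderGraph:
    def __init__(self) -> None:
        self.nodes: dict[str, RenderNode] = {}
        self.edges: dict[str, RenderEdge] = {}
        self.bands: list[tuple[str, float, float]] = []
        self.step_stamps = {"topology": 0, "attributes": 0, "layout": 0}
        self.engine: Optional[str] = None
        self.engine_opts: dict[str, Any] = {}

    def __eq__(self, other: object) -> bool:  # stamps deliberately excluded
        if not isinstance(other, RenderGraph):
            return NotImplemented
        return (self.nodes == other.nodes and self.edges == other.edges
                and self.bands == other.bands)

    def __repr__(self) -> str:
        return f"<RenderGraph {len(self.nodes)} nodes, {len(self.edges)} edges>"


# -- step 1: topology -------------------------------------------------------

def _endpoint(model: NetworkModel, ref: str) -> Optional[str]:
    """Resolve an edge endpoint to the render node that stands for it."""
    if ref in model.aliases:
        node = ref
    elif ref in model.entities and model.instances_of(ref):
        node = model.instances_of(ref)[0]  # entity drawn only via instances
    else:
        node = ref
    root = model.collapse_root(node)
    if root is not None:
        if model.groups[root].semantics is GroupSemantics.REACTION_COFACTORS:
            return None  # hidden co-factors: no re-attachment, just hidden
        node = root
    if not model.has(node) or not model.resolve_property(node, "visible"):
        return None
    return node


def _node_visible(model: NetworkModel, cid: str) -> bool:
    if model.is_hidden_by_collapse(cid):
        return False
    return bool(model.resolve_property(cid, "visible"))


def build_topology(model: NetworkModel) -> RenderGraph:
    """Step 1: flatten the hierarchical model into drawable nodes and edges."""
    rg = RenderGraph()

    aliased = {eid for eid in model.entities if model.instances_of(eid)}
    for eid in sorted(model.entities):
        if eid in aliased or not _node_visible(model, eid):
            continue
        rg.nodes[eid] = RenderNode(eid, origin=eid, kind="entity")
    for iid in sorted(model.aliases):
        if not _node_visible(model, iid):
            continue
        rg.nodes[iid] = RenderNode(iid, origin=iid, kind="alias")
    for gid in sorted(model.groups):
        g = model.groups[gid]
        if not _node_visible(model, gid):
            continue
        if g.collapsed and g.semantics is not GroupSemantics.REACTION_COFACTORS:
            rg.nodes[gid] = RenderNode(gid, origin=gid, kind="group")
    for rid in sorted(model.reactions):
        if not _node_visible(model, rid):
            continue
        rg.nodes[rid] = RenderNode(rid, origin=rid, kind="reaction")

    # binary edges, re-attached through collapse/alias resolution and merged
    buckets: dict[tuple, list[str]] = {}
    for eid in sorted(model.edges):
        e = model.edges[eid]
        if not model.resolve_property(eid, "visible"):
            continue
        s = _endpoint(model, e.source)
        t = _endpoint(model, e.target)
        if s is None or t is None or s not in rg.nodes or t not in rg.nodes:
            continue
        if s == t and e.source != e.target:
            continue  # edge swallowed inside a collapsed group
        key = (s, t, e.directed) if e.directed else (min(s, t), max(s, t), False)
        buckets.setdefault(key, []).append(eid)
    for (s, t, directed), eids in sorted(buckets.items()):
        relations = {model.edges[i].relation for i in eids}
        relation = relations.pop() if len(relations) == 1 else Relation.GENERIC
        mult = sum(model.edges[i].multiplicity for i in eids)
        reattached = any(
            model.edges[i].source != s or model.edges[i].target != t for i in eids
        )
        if len(eids) == 1 and not reattached:
            rid = eids[0]
            kind = "edge"
        else:
            rid = f"agg:{s}->{t}:{relation.value}"
            kind = "aggregate" if (reattached or len(eids) > 1) else "edge"
        rg.edges[rid] = RenderEdge(
            rid, origins=tuple(eids), source=s, target=t,
            relation=relation.value, directed=directed,
            multiplicity=mult, kind=kind,
        )

    # reaction hyperedges expand to bipartite stars around the reaction node
    for rid in sorted(model.reactions):
        if rid not in rg.nodes:
            continue
        rxn = model.reactions[rid]
        reverse = model.resolve_property(rid, "direction") == "reverse"
        for (pid, _stoich) in sorted(rxn.substrates):
            p = _endpoint(model, pid)
            if p is None or p not in rg.nodes:
                continue
            eid = f"{rid}:sub:{p}"
            src, tgt = (p, rid) if not reverse else (rid, p)
            rg.edges[eid] = RenderEdge(
                eid, origins=(rid,), source=src, target=tgt,
                relation="reaction", directed=True, kind="reaction_sub")
        for (pid, _stoich) in sorted(rxn.products):
            p = _endpoint(model, pid)
            if p is None or p not in rg.nodes:
                continue
            eid = f"{rid}:prod:{p}"
            src, tgt = (rid, p) if not reverse else (p, rid)
            rg.edges[eid] = RenderEdge(
                eid, origins=(rid,), source=src, target=tgt,
                relation="reaction", directed=True, kind="reaction_prod")
        for cid in sorted(rxn.catalysts):
            c = _endpoint(model, cid)
            if c is None or c not in rg.nodes:
                continue
            eid = f"{rid}:cat:{c}"
            rg.edges[eid] = RenderEdge(
                eid, origins=(rid,), source=c, target=rid,
                relation="catalysis", directed=False, kind="catalysis")

    # star groups: satellites attach radially to the hub member
    for gid in sorted(model.groups):
        g = model.groups[gid]
        if g.semantics is not GroupSemantics.STAR or g.collapsed or g.hub_id is None:
            continue
        hub = _endpoint(model, g.hub_id)
        if hub is None or hub not in rg.nodes:
            continue
        for m in g.member_ids:
            if m == g.hub_id:
                continue
            sat = _endpoint(model, m)
            if sat is None or sat not in rg.nodes or sat == hub:
                continue
            eid = f"{gid}:star:{sat}"
            rg.edges[eid] = RenderEdge(
                eid, origins=(gid,), source=hub, target=sat,
                relation="star", directed=False, kind="star")

    rg.step_stamps["topology"] += 1
    return rg


# -- step 2: attributes -----------------------------------------------------

def _resolve_node_props(model: NetworkModel, node: RenderNode) -> None:
    props = {p: model.resolve_property(node.origin, p) for p in RESOLVED_PROPS}
    shape = props["shape"]
    if isinstance(shape, GlyphSpec):
        node.glyph = shape
        props["shape"] = "glyph"
        props["size"] = GLYPH_BOX
    else:
        node.glyph = None
    node.props = props


def assign_attributes(rg: RenderGraph, model: NetworkModel) -> RenderGraph:
    """Step 2: resolve the full property set of every drawable element."""
    if rg.step_stamps["topology"] == 0:
        raise StateError("assign_attributes called before build_topology")
    for node in rg.nodes.values():
        _resolve_node_props(model, node)
    for edge in rg.edges.values():
        if len(edge.origins) == 1 and edge.origins[0] in model.edges:
            origin = edge.origins[0]
            edge.props = {
                "stroke_color": model.resolve_property(origin, "stroke_color"),
                "line_width": model.resolve_property(origin, "line_width"),
            }
        else:
            edge.props = {"stroke_color": "#000000", "line_width": 1.0}
    rg.step_stamps["attributes"] += 1
    return rg


# -- step 3: layout ---------------------------------------------------------

def apply_layout(
    rg: RenderGraph,
    model: NetworkModel,
    engine: str = "force",
    opts: Optional[dict[str, Any]] = None,
) -> RenderGraph:
    """Step 3: position nodes and route edges with the chosen engine.

    Groups carrying ``own_layout`` (and expanded) get their members laid out
    independently by that engine, then the block is re-centered where the
    parent layout placed the members — several layouts can coexist in one
    view.
    """
    if rg.step_stamps["attributes"] == 0:
        raise StateError("apply_layout called before assign_attributes")
    opts = dict(opts or {})
    seed = int(opts.get("seed", 0))

    sizes = {nid: tuple(map(float, n.props["size"])) for nid, n in rg.nodes.items()}
    edge_list = [(eid, e.source, e.target) for eid, e in sorted(rg.edges.items())]

    if engine == "force":
        roles: dict[str, dict[str, str]] = {}
        flow: dict[str, tuple[list[str], list[str]]] = {}
        for rid, rxn in model.reactions.items():
            if rid not in rg.nodes:
                continue
            role_map = {}
            for pid, _ in rxn.substrates:
                if pid in rxn.cofactors and pid in rg.nodes:
                    role_map[pid] = "in"
            for pid, _ in rxn.products:
                if pid in rxn.cofactors and pid in rg.nodes:
                    role_map[pid] = "out"
            if role_map:
                roles[rid] = role_map
                flow[rid] = (
                    [s for s, _ in rxn.substrates
                     if s not in rxn.cofactors and s in rg.nodes],
                    [p for p, _ in rxn.products
                     if p not in rxn.cofactors and p in rg.nodes],
                )
        result = layout_force(
            sizes, edge_list,
            iterations=int(opts.get("iterations", 50)), seed=seed,
            cofactor_orbit_radius=float(opts.get("cofactor_orbit_radius", 60.0)),
            cofactor_roles=roles,
            reaction_flow=flow,
        )
    elif engine == "layered":
        cm = opts.get("compartment_model") or CompartmentModel()
        layer_map = opts.get("layer_map")
        if layer_map is None:
            layer_map, _ = assign_layers(model, cm)
        layer_map = {n: layer_map.get(n, cm.layers.index(cm.fallback))
                     for n in sizes}
        result = layout_layered(sizes, edge_list, layer_map, band_names=cm.layers)
    elif engine == "kegg":
        hints = opts.get("hints")
        if hints is None:
            raise ConfigError("kegg layout engine needs KGML hints in opts['hints']")
        rxn_edges = {eid for eid, e in rg.edges.items()
                     if e.kind in ("reaction_sub", "reaction_prod")}
        result = layout_kegg(sizes, edge_list, hints,
                             reaction_edge_ids=rxn_edges, seed=seed)
    else:
        raise ConfigError(f"unknown layout engine {engine!r}")

    # per-group own layouts, re-centered inside the parent drawing
    for gid in sorted(model.groups):
        g = model.groups[gid]
        if g.collapsed or not g.own_layout or g.own_layout == engine:
            continue
        members = [m for m in g.member_ids if m in rg.nodes]
        if len(members) < 2:
            continue
        member_set = set(members)
        sub_edges = [(eid, u, v) for eid, u, v in edge_list
                     if u in member_set and v in member_set]
        sub_sizes = {m: sizes[m] for m in members}
        if g.own_layout == "layered":
            cm = opts.get("compartment_model") or CompartmentModel()
            lm, _ = assign_layers(model, cm)
            lm = {n: lm.get(n, cm.layers.index(cm.fallback)) for n in sub_sizes}
            sub = layout_layered(sub_sizes, sub_edges, lm, band_names=cm.layers)
        elif g.own_layout == "force":
            sub = layout_force(sub_sizes, sub_edges, seed=seed)
        else:
            raise ConfigError(f"unknown own_layout {g.own_layout!r} on group {gid!r}")
        cx = sum(result.positions[m][0] for m in members) / len(members)
        cy = sum(result.positions[m][1] for m in members) / len(members)
        sx = sum(sub.positions[m][0] for m in members) / len(members)
        sy = sum(sub.positions[m][1] for m in members) / len(members)
        for m in members:
            x, y, w, h = sub.positions[m]
            result.positions[m] = (x - sx + cx, y - sy + cy, w, h)
        for eid, u, v in sub_edges:
            result.routes[eid] = ("straight", [
                (result.positions[u][0], result.positions[u][1]),
                (result.positions[v][0], result.positions[v][1])])

    _merge_layout(rg, result)
    rg.engine = engine
    rg.engine_opts = opts
    rg.step_stamps["layout"] += 1
    return rg


def _merge_layout(rg: RenderGraph, result: LayoutResult) -> None:
    for nid, node in rg.nodes.items():
        if nid in result.positions:
            node.geometry = result.positions[nid]
    for eid, edge in rg.edges.items():
        route = result.routes.get(eid)
        if route is None and edge.source in result.positions \
                and edge.target in result.positions:
            route = ("straight", [
                (result.positions[edge.source][0], result.positions[edge.source][1]),
                (result.positions[edge.target][0], result.positions[edge.target][1]),
            ])
        if route is not None and edge.kind in ("reaction_sub", "reaction_prod") \
                and route[0] == "straight":
            p, q = route[1][0], route[1][-1]
            route = ("quadratic", [p, _quad_ctrl(p, q), q])
        edge.route = route
    rg.bands = list(result.bands)


def _quad_ctrl(p, q, bulge: float = 0.18):
    mx, my = (p[0] + q[0]) / 2, (p[1] + q[1]) / 2
    dx, dy = q[0] - p[0], q[1] - p[1]
    return (mx - dy * bulge, my + dx * bulge)


def full_render(
    model: NetworkModel,
    engine: str = "force",
    opts: Optional[dict[str, Any]] = None,
) -> RenderGraph:
    """Run all three steps from scratch and clear the model's dirty flags."""
    rg = build_topology(model)
    assign_attributes(rg, model)
    apply_layout(rg, model, engine, opts)
    model.clear_dirty()
    return rg


# -- incremental update -----------------------------------------------------

def incremental_update(model: NetworkModel, rg: RenderGraph) -> RenderGraph:
    """Re-render only what the model's dirty flags require.

    Topological dirt rebuilds all three steps; visual dirt re-resolves
    attributes of the affected elements only; layout dirt re-runs the layout
    step.  The result equals a from-scratch render — that equivalence is the
    operation's contract.
    """
    if rg.step_stamps["layout"] == 0:
        raise StateError("incremental_update needs a fully rendered graph")
    if not model.dirty:
        return rg
    kinds = set().union(*model.dirty.values())
    engine = rg.engine or "force"
    opts = rg.engine_opts

    if Dirty.TOPOLOGICAL in kinds:
        new_rg = build_topology(model)
        assign_attributes(new_rg, model)
        apply_layout(new_rg, model, engine, opts)
        rg.nodes, rg.edges, rg.bands = new_rg.nodes, new_rg.edges, new_rg.bands
        rg.step_stamps["topology"] += 1
        rg.step_stamps["attributes"] += 1
        rg.step_stamps["layout"] += 1
        model.clear_dirty()
        return rg

    if Dirty.VISUAL in kinds:
        dirty_ids = {cid for cid, ks in model.dirty.items() if Dirty.VISUAL in ks}
        for node in rg.nodes.values():
            if node.origin in dirty_ids:
                _resolve_node_props(model, node)
        for edge in rg.edges.values():
            if any(o in dirty_ids for o in edge.origins) \
                    and len(edge.origins) == 1 and edge.origins[0] in model.edges:
                origin = edge.origins[0]
                edge.props = {
                    "stroke_color": model.resolve_property(origin, "stroke_color"),
                    "line_width": model.resolve_property(origin, "line_width"),
                }
        rg.step_stamps["attributes"] += 1
        # a size change moves geometry too
        kinds.add(Dirty.LAYOUT)

    if Dirty.LAYOUT in kinds:
        apply_layout(rg, model, engine, opts)

    model.clear_dirty()
    return rg


# -- SVG output -------------------------------------------------------------

def _fmt(v: float) -> str:
    return f"{v:.2f}".rstrip("0").rstrip(".")


def _esc(text: str) -> str:
    return (str(text).replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;").replace('"', "&quot;"))


def _shape_svg(shape: str, x: float, y: float, w: float, h: float,
               fill: str, stroke: str, width: float) -> str:
    style = (f'fill="{_esc(fill)}" stroke="{_esc(stroke)}" '
             f'stroke-width="{_fmt(width)}"')
    if shape in ("ellipse", "circle", "small_circle"):
        rx, ry = (w / 2, h / 2)
        if shape == "circle":
            rx = ry = min(w, h) / 2
        if shape == "small_circle":
            rx = ry = min(w, h) / 4
        return (f'<ellipse cx="{_fmt(x)}" cy="{_fmt(y)}" rx="{_fmt(rx)}" '
                f'ry="{_fmt(ry)}" {style}/>')
    if shape == "rounded_rect":
        return (f'<rect x="{_fmt(x - w / 2)}" y="{_fmt(y - h / 2)}" '
                f'width="{_fmt(w)}" height="{_fmt(h)}" rx="6" {style}/>')
    if shape == "parallelogram":
        skew = w * 0.15
        pts = [(x - w / 2 + skew, y - h / 2), (x + w / 2, y - h / 2),
               (x + w / 2 - skew, y + h / 2), (x - w / 2, y + h / 2)]
        p = " ".join(f"{_fmt(px)},{_fmt(py)}" for px, py in pts)
        return f'<polygon points="{p}" {style}/>'
    if shape == "octagon":
        c = min(w, h) * 0.25
        pts = [(x - w / 2 + c, y - h / 2), (x + w / 2 - c, y - h / 2),
               (x + w / 2, y - h / 2 + c), (x + w / 2, y + h / 2 - c),
               (x + w / 2 - c, y + h / 2), (x - w / 2 + c, y + h / 2),
               (x - w / 2, y + h / 2 - c), (x - w / 2, y - h / 2 + c)]
        p = " ".join(f"{_fmt(px)},{_fmt(py)}" for px, py in pts)
        return f'<polygon points="{p}" {style}/>'
    # rect and anything unknown
    return (f'<rect x="{_fmt(x - w / 2)}" y="{_fmt(y - h / 2)}" '
            f'width="{_fmt(w)}" height="{_fmt(h)}" {style}/>')


def _glyph_svg(glyph: GlyphSpec, x: float, y: float) -> str:
    """Mini bar/line chart in a fixed box replacing the node shape."""
    w, h = GLYPH_BOX
    x0, y0 = x - w / 2, y - h / 2
    vals = glyph.values
    finite = [v for v in vals if not math.isnan(v)]
    lo = min(finite + [0.0])
    hi = max(finite + [0.0])
    span = (hi - lo) or 1.0
    parts = [f'<g class="glyph">',
             f'<rect x="{_fmt(x0)}" y="{_fmt(y0)}" width="{_fmt(w)}" '
             f'height="{_fmt(h)}" fill="#FFFFFF" stroke="#000000" '
             f'stroke-width="0.5"/>']
    inner_h = h - 10
    if glyph.kind == "bar":
        bw = w / max(len(vals), 1)
        for i, v in enumerate(vals):
            if math.isnan(v):
                continue
            frac = (v - lo) / span
            bh = max(inner_h * frac, 0.5)
            parts.append(
                f'<rect x="{_fmt(x0 + i * bw + 1)}" '
                f'y="{_fmt(y0 + 5 + inner_h - bh)}" width="{_fmt(bw - 2)}" '
                f'height="{_fmt(bh)}" fill="#4477AA" stroke="none"/>')
    else:
        pts = []
        step = w / max(len(vals) - 1, 1)
        for i, v in enumerate(vals):
            if math.isnan(v):
                continue
            frac = (v - lo) / span
            pts.append(f"{_fmt(x0 + i * step)},{_fmt(y0 + 5 + inner_h * (1 - frac))}")
        if len(pts) >= 2:
            parts.append(f'<polyline points="{" ".join(pts)}" fill="none" '
                         f'stroke="#4477AA" stroke-width="1.5"/>')
    # min/max tick labels annotate the scale
    parts.append(f'<text x="{_fmt(x0 + 1)}" y="{_fmt(y0 + 4.5)}" '
                 f'font-size="4">{_fmt(hi)}</text>')
    parts.append(f'<text x="{_fmt(x0 + 1)}" y="{_fmt(y0 + h - 1)}" '
                 f'font-size="4">{_fmt(lo)}</text>')
    parts.append("</g>")
    return "".join(parts)


def _route_path(edge: RenderEdge) -> str:
    kind, pts = edge.route
    style = (f'fill="none" stroke="{_esc(edge.props.get("stroke_color", "#000000"))}" '
             f'stroke-width="{_fmt(float(edge.props.get("line_width", 1.0)))}"')
    marker = ' marker-end="url(#arrow)"' if edge.directed else ""
    if edge.relation == "inhibition":
        marker = ' marker-end="url(#tbar)"'
    dash = ' stroke-dasharray="4 2"' if edge.kind == "catalysis" else ""
    if kind == "quadratic" and len(pts) == 3:
        d = (f"M {_fmt(pts[0][0])} {_fmt(pts[0][1])} "
             f"Q {_fmt(pts[1][0])} {_fmt(pts[1][1])} "
             f"{_fmt(pts[2][0])} {_fmt(pts[2][1])}")
        return f'<path d="{d}" {style}{dash}{marker}/>'
    coords = " L ".join(f"{_fmt(px)} {_fmt(py)}" for px, py in pts)
    return f'<path d="M {coords}" {style}{dash}{marker}/>'


def render_svg(rg: RenderGraph, padding: float = 20.0,
               show_bands: bool = True) -> str:
    """Emit deterministic SVG 1.1 text for a fully rendered graph."""
    if rg.step_stamps["layout"] == 0:
        raise StateError("render_svg needs a laid-out graph")
    xs, ys = [0.0], [0.0]
    for n in rg.nodes.values():
        if n.geometry is None:
            raise StateError(f"node {n.id!r} has no geometry")
        x, y, w, h = n.geometry
        xs += [x - w / 2, x + w / 2]
        ys += [y - h / 2, y + h / 2]
    for _, y0, y1 in rg.bands:
        ys += [y0, y1]
    width = max(xs) + padding
    height = max(ys) + padding

    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">',
        '<defs>'
        '<marker id="arrow" viewBox="0 0 10 10" refX="9" refY="5" '
        'markerWidth="7" markerHeight="7" orient="auto-start-reverse">'
        '<path d="M 0 0 L 10 5 L 0 10 z" fill="#000000"/></marker>'
        '<marker id="tbar" viewBox="0 0 10 10" refX="9" refY="5" '
        'markerWidth="7" markerHeight="7" orient="auto">'
        '<path d="M 8 0 L 8 10" stroke="#000000" stroke-width="2" fill="none"/>'
        '</marker></defs>',
    ]

    if show_bands and rg.bands:
        shades = ["#F4F7FB", "#E8EEF6"]
        for i, (name, y0, y1) in enumerate(rg.bands):
            out.append(f'<rect x="0" y="{_fmt(y0)}" width="{_fmt(width)}" '
                       f'height="{_fmt(y1 - y0)}" fill="{shades[i % 2]}" '
                       f'stroke="none"/>')
            out.append(f'<text x="4" y="{_fmt(y0 + 12)}" font-size="10" '
                       f'fill="#8899AA">{_esc(name)}</text>')

    for eid in sorted(rg.edges):
        edge = rg.edges[eid]
        if edge.route is None:
            continue
        out.append(_route_path(edge))
        if edge.multiplicity > 1:
            pts = edge.route[1]
            mid = pts[len(pts) // 2] if len(pts) > 2 else (
                (pts[0][0] + pts[-1][0]) / 2, (pts[0][1] + pts[-1][1]) / 2)
            out.append(f'<text x="{_fmt(mid[0])}" y="{_fmt(mid[1] - 3)}" '
                       f'font-size="9" text-anchor="middle">'
                       f'x{edge.multiplicity}</text>')

    for nid in sorted(rg.nodes):
        node = rg.nodes[nid]
        x, y, w, h = node.geometry
        if node.glyph is not None:
            out.append(_glyph_svg(node.glyph, x, y))
        else:
            out.append(_shape_svg(
                str(node.props.get("shape", "ellipse")), x, y, w, h,
                str(node.props.get("fill_color", "#FFFFFF")),
                str(node.props.get("stroke_color", "#000000")),
                float(node.props.get("line_width", 1.0)),
            ))
        label = str(node.props.get("label", ""))
        if label and node.glyph is None:
            out.append(f'<text x="{_fmt(x)}" y="{_fmt(y + 3)}" font-size="9" '
                       f'text-anchor="middle">{_esc(label)}</text>')

    out.append("</svg>")
    return "\n".join(out) + "\n"
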