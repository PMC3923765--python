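"""Layout engines.

Three engines share one output type (:class:`LayoutResult`):

* ``layered`` — Sugiyama-style drawing in horizontal bands; the band of a
  node comes from its subcellular compartment (extracellular topmost, nucleus
  at the bottom), so signaling cascades read top-to-bottom.  Crossing
  reduction is iterative barycenter with a fixed sweep count; edges spanning
  several bands are routed through internal dummy nodes.
* ``force`` — Fruchterman–Reingold placement with a fixed seed; afterwards
  each reaction's co-factors are re-placed on an arc around the reaction
  node, consumed co-factors on the incoming side of the reaction flow and
  produced ones on the outgoing side.
* ``kegg`` — fixed positions copied verbatim from KGML hints; un-hinted nodes
  are placed by the force engine inside the hinted bounding box; edge routes
  are straight unless the segment would cross a node body, in which case a
  two-bend orthogonal route is used.  Reaction arrows are quadratic curves.

All engines are deterministic for a fixed input and seed; ties break by
lexicographic node id.  Coordinates are pixels, origin top-left, y downward.
A minimum-separation post-pass removes node-body overlaps.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigError
from .model import NetworkModel

BAND_HEIGHT = 120.0
NODE_SPACING_X = 90.0
MARGIN = 60.0
#: above this node count the force engine switches to sparse spectral
#: placement (pairwise Fruchterman–Reingold is quadratic in n)
FORCE_EXACT_LIMIT = 1500
BARYCENTER_SWEEPS = 8


@dataclass
class CompartmentModel:
    """Ordered subcellular layers (top to bottom) plus term aliases."""

    layers: list[str] = field(default_factory=lambda: [
        "extracellular", "plasma_membrane", "cytoplasm",
        "nuclear_membrane", "nucleus",
    ])
    term_map: dict[str, str] = field(default_factory=dict)
    fallback: str = "cytoplasm"

    def __post_init__(self) -> None:
        if len(set(self.layers)) != len(self.layers):
            raise ConfigError("duplicate layer names in compartment model")
        defaults = {
            "extracellular space": "extracellular",
            "extracellular region": "extracellular",
            "cell membrane": "plasma_membrane",
            "membrane": "plasma_membrane",
            "cytosol": "cytoplasm",
            "nuclear envelope": "nuclear_membrane",
        }
        for k, v in defaults.items():
            self.term_map.setdefault(k, v)
        for layer in self.layers:
            self.term_map.setdefault(layer, layer)
        for term, layer in self.term_map.items():
            if layer not in self.layers:
                raise ConfigError(f"term {term!r} maps to unknown layer {layer!r}")
        if self.fallback not in self.layers:
            raise ConfigError(f"fallback layer {self.fallback!r} not in layer list")

    def layer_index(self, term: str) -> Optional[int]:
        layer = self.term_map.get(term)
        return self.layers.index(layer) if layer is not None else None

    @classmethod
    def from_dict(cls, data: dict) -> "CompartmentModel":
        kwargs = {}
        if data.get("layers"):
            kwargs["layers"] = list(data["layers"])
        if data.get("term_map"):
            kwargs["term_map"] = dict(data["term_map"])
        if data.get("fallback"):
            kwargs["fallback"] = data["fallback"]
        return cls(**kwargs)


@dataclass
class LayoutResult:
    """Node geometry plus edge routes.

    ``positions``: node id -> (x, y, w, h) with (x, y) the node center.
    ``routes``: edge id -> (curve kind, control points); kinds are
    ``straight``, ``quadratic`` and ``orthogonal``.
    """

    positions: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    routes: dict[str, tuple[str, list[tuple[float, float]]]] = field(default_factory=dict)
    bands: list[tuple[str, float, float]] = field(default_factory=list)  # (name, y0, y1)

    def __post_init__(self) -> None:
        for nid, (x, y, w, h) in self.positions.items():
            if not all(math.isfinite(v) for v in (x, y, w, h)):
                raise ConfigError(f"non-finite coordinates for node {nid!r}")


# -- layer assignment -------------------------------------------------------

def assign_layers(
    model: NetworkModel, cm: CompartmentModel
) -> tuple[dict[str, int], dict[str, int]]:
    """Assign each node component a band index from its compartment terms.

    The topmost mapped layer wins when terms map to several layers; the
    ambiguity count per node is the number of *distinct* mapped layers (0 for
    an unannotated node, which lands in the fallback layer).
    """
    layer_of: dict[str, int] = {}
    ambiguity: dict[str, int] = {}
    fallback_idx = cm.layers.index(cm.fallback)
    for cid in model.node_component_ids():
        comp = model.component(cid)
        terms = list(getattr(comp, "compartments", []) or [])
        if cid in model.aliases:
            terms = list(model.entities[model.aliases[cid].entity_id].compartments)
        mapped = sorted({idx for t in terms
                         if (idx := cm.layer_index(t)) is not None})
        ambiguity[cid] = len(mapped)
        layer_of[cid] = mapped[0] if mapped else fallback_idx
    return layer_of, ambiguity


# -- layered (Sugiyama) -----------------------------------------------------

def _count_crossings(order: dict[str, int], layer_of: dict[str, int],
                     edges: Sequence[tuple[str, str]]) -> int:
    count = 0
    spans = [(u, v) if layer_of[u] <= layer_of[v] else (v, u) for u, v in edges]
    for (a1, b1), (a2, b2) in itertools.combinations(spans, 2):
        if layer_of[a1] != layer_of[a2] or layer_of[b1] != layer_of[b2]:
            continue
        if (order[a1] - order[a2]) * (order[b1] - order[b2]) < 0:
            count += 1
    return count


def layout_layered(
    nodes: dict[str, tuple[float, float]],
    edges: Sequence[tuple[str, str, str]],
    layer_map: dict[str, int],
    band_names: Optional[Sequence[str]] = None,
) -> LayoutResult:
    """Sugiyama layered layout with fixed layer assignment.

    ``nodes`` maps id -> (width, height); ``edges`` are (id, source, target).
    Within-band order starts lexicographic and is refined by
    :data:`BARYCENTER_SWEEPS` alternating barycenter sweeps; the best ordering
    seen (by crossing count) is kept, so the result never has more crossings
    than the initial ordering.  Long edges are routed through dummy nodes and
    emitted as polylines.
    """
    for nid in nodes:
        if nid not in layer_map:
            raise ConfigError(f"node {nid!r} has no layer assignment")
    n_layers = (max(layer_map[n] for n in nodes) + 1) if nodes else 0

    # dummy nodes for edges spanning > 1 layer
    seg_edges: list[tuple[str, str]] = []
    edge_chain: dict[str, list[str]] = {}
    layer_of = {n: layer_map[n] for n in nodes}
    dummy_count = 0
    for eid, u, v in edges:
        lu, lv = layer_of[u], layer_of[v]
        if u == v or abs(lu - lv) <= 1:
            seg_edges.append((u, v))
            edge_chain[eid] = [u, v]
            continue
        lo_node, hi_node = (u, v) if lu < lv else (v, u)
        chain = [lo_node]
        for layer in range(min(lu, lv) + 1, max(lu, lv)):
            dummy_count += 1
            d = f"__dummy_{dummy_count}"
            layer_of[d] = layer
            chain.append(d)
        chain.append(hi_node)
        for a, b in zip(chain, chain[1:]):
            seg_edges.append((a, b))
        edge_chain[eid] = chain if lu < lv else chain[::-1]

    by_layer: dict[int, list[str]] = {i: [] for i in range(n_layers)}
    for n, layer in layer_of.items():
        by_layer.setdefault(layer, []).append(n)
    for layer in by_layer:
        by_layer[layer].sort()

    neighbors_down: dict[str, list[str]] = {n: [] for n in layer_of}
    neighbors_up: dict[str, list[str]] = {n: [] for n in layer_of}
    for a, b in seg_edges:
        if layer_of[a] == layer_of[b]:
            continue
        lo, hi = (a, b) if layer_of[a] < layer_of[b] else (b, a)
        neighbors_down[hi].append(lo)
        neighbors_up[lo].append(hi)

    def current_order() -> dict[str, int]:
        return {n: i for layer in sorted(by_layer) for i, n in enumerate(by_layer[layer])}

    best_order = current_order()
    best_crossings = _count_crossings(best_order, layer_of, seg_edges)

    for sweep in range(BARYCENTER_SWEEPS):
        downward = sweep % 2 == 0
        layers_iter = sorted(by_layer) if downward else sorted(by_layer, reverse=True)
        order = current_order()
        for layer in layers_iter:
            refs = neighbors_down if downward else neighbors_up
            def key(n):
                nbrs = refs[n]
                if not nbrs:
                    return (order[n], n)
                return (sum(order[m] for m in nbrs) / len(nbrs), n)
            by_layer[layer] = sorted(by_layer[layer], key=key)
            order = current_order()
        crossings = _count_crossings(order, layer_of, seg_edges)
        if crossings < best_crossings:
            best_crossings, best_order = crossings, order

    # restore the best ordering
    for layer in by_layer:
        by_layer[layer].sort(key=lambda n: best_order[n])

    positions: dict[str, tuple[float, float, float, float]] = {}
    dummy_pos: dict[str, tuple[float, float]] = {}
    max_width = max((len(v) for v in by_layer.values()), default=1)
    for layer in sorted(by_layer):
        row = by_layer[layer]
        y = MARGIN + BAND_HEIGHT * layer + BAND_HEIGHT / 2
        offset = (max_width - len(row)) * NODE_SPACING_X / 2
        for i, n in enumerate(row):
            x = MARGIN + offset + i * NODE_SPACING_X
            if n.startswith("__dummy_"):
                dummy_pos[n] = (x, y)
            else:
                w, h = nodes[n]
                positions[n] = (x, y, w, h)

    _separate_overlaps(positions, same_row_only=True)

    routes: dict[str, tuple[str, list[tuple[float, float]]]] = {}
    for eid, chain in edge_chain.items():
        pts = []
        for n in chain:
            if n in dummy_pos:
                pts.append(dummy_pos[n])
            else:
                x, y, _, _ = positions[n]
                pts.append((x, y))
        routes[eid] = ("straight", pts)

    bands = []
    names = list(band_names) if band_names else [f"layer {i}" for i in range(n_layers)]
    for i in range(n_layers):
        name = names[i] if i < len(names) else f"layer {i}"
        bands.append((name, MARGIN + BAND_HEIGHT * i, MARGIN + BAND_HEIGHT * (i + 1)))
    return LayoutResult(positions=positions, routes=routes, bands=bands)


# -- force ------------------------------------------------------------------

def layout_force(
    nodes: dict[str, tuple[float, float]],
    edges: Sequence[tuple[str, str, str]],
    iterations: int = 50,
    seed: int = 0,
    cofactor_orbit_radius: float = 60.0,
    cofactor_roles: Optional[dict[str, dict[str, str]]] = None,
    reaction_flow: Optional[dict[str, tuple[list[str], list[str]]]] = None,
    scale: float = 300.0,
    ideal_edge_length: float = 80.0,
) -> LayoutResult:
    """Organic (force-directed) layout with co-factor flow placement.

    After the force iteration, positions are rescaled so the median edge
    length equals ``ideal_edge_length`` (pixels) — edge lengths stay
    comparable across graph sizes instead of stretching to fill a canvas.

    ``cofactor_roles`` maps a reaction node id to {co-factor node id:
    "in"|"out"}; those co-factors are then re-placed on an arc of
    ``cofactor_orbit_radius`` around the reaction node — consumed ones on the
    incoming side of the substrate->product direction, produced ones on the
    outgoing side.  Deterministic for a fixed seed.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for _, u, v in edges:
        if u != v:
            g.add_edge(u, v)
    if len(g) == 0:
        return LayoutResult()

    if len(g) <= FORCE_EXACT_LIMIT:
        pos = nx.spring_layout(g, iterations=iterations, seed=seed,
                               center=(0.0, 0.0))
        arr = {n: (float(p[0]) * scale, float(p[1]) * scale)
               for n, p in pos.items()}
    else:
        # dynamic setting for large graphs: pairwise repulsion is quadratic,
        # so fall back to seeded random placement refined by vectorized
        # neighbor-averaging sweeps (linear in the edge count)
        order = sorted(g)
        index = {n: i for i, n in enumerate(order)}
        n = len(order)
        rng = np.random.default_rng(seed)
        p = rng.uniform(-1.0, 1.0, size=(n, 2))
        if g.number_of_edges():
            src = np.fromiter((index[u] for u, v in g.edges()), dtype=np.int64)
            dst = np.fromiter((index[v] for u, v in g.edges()), dtype=np.int64)
            deg = np.zeros(n)
            np.add.at(deg, src, 1.0)
            np.add.at(deg, dst, 1.0)
            for _ in range(10):
                acc = np.zeros((n, 2))
                np.add.at(acc, src, p[dst])
                np.add.at(acc, dst, p[src])
                mean = acc / np.maximum(deg, 1.0)[:, None]
                p = 0.6 * p + 0.4 * mean
                p -= p.mean(axis=0)
                extent = np.abs(p).max() or 1.0
                p /= extent
        big_scale = scale * math.sqrt(n) / 4.0
        arr = {node: (float(p[i, 0]) * big_scale, float(p[i, 1]) * big_scale)
               for node, i in index.items()}

    # normalize so the median edge length hits the target
    lengths = sorted(
        math.hypot(arr[u][0] - arr[v][0], arr[u][1] - arr[v][1])
        for u, v in itertools.islice(g.edges(), 10000) if u != v
    )
    if lengths and lengths[len(lengths) // 2] > 0:
        factor = ideal_edge_length / lengths[len(lengths) // 2]
        arr = {n_: (x * factor, y * factor) for n_, (x, y) in arr.items()}

    # co-factor satellites around their reaction node
    for rxn_node in sorted(cofactor_roles or {}):
        roles = cofactor_roles[rxn_node]
        if rxn_node not in arr:
            continue
        rx, ry = arr[rxn_node]
        # reaction flow direction: from main substrates toward main products
        ups, downs = (reaction_flow or {}).get(rxn_node, ([], []))
        ups = [n for n in ups if n in arr and n not in roles]
        downs = [n for n in downs if n in arr and n not in roles]
        if not ups and not downs:
            ups = [n for n in g.neighbors(rxn_node) if n not in roles]
        fx = fy = 0.0
        if ups:
            fx += rx - sum(arr[n][0] for n in ups) / len(ups)
            fy += ry - sum(arr[n][1] for n in ups) / len(ups)
        if downs:
            fx += sum(arr[n][0] for n in downs) / len(downs) - rx
            fy += sum(arr[n][1] for n in downs) / len(downs) - ry
        norm = math.hypot(fx, fy)
        flow = (fx / norm, fy / norm) if norm else (1.0, 0.0)
        ins = sorted(n for n, side in roles.items() if side == "in" and n in arr)
        outs = sorted(n for n, side in roles.items() if side == "out" and n in arr)
        for side_sign, members in ((-1.0, ins), (1.0, outs)):
            for i, n in enumerate(members):
                spread = (i - (len(members) - 1) / 2) * (math.pi / 6)
                base = math.atan2(flow[1], flow[0])
                ang = base + (0.0 if side_sign > 0 else math.pi) + spread
                arr[n] = (rx + cofactor_orbit_radius * math.cos(ang),
                          ry + cofactor_orbit_radius * math.sin(ang))

    positions = {}
    min_x = min(p[0] for p in arr.values())
    min_y = min(p[1] for p in arr.values())
    for n, (x, y) in arr.items():
        w, h = nodes.get(n, (40.0, 20.0))
        positions[n] = (x - min_x + MARGIN, y - min_y + MARGIN, w, h)

    if len(g) <= FORCE_EXACT_LIMIT:
        _separate_overlaps(positions)

    routes = {eid: ("straight", [_center(positions[u]), _center(positions[v])])
              for eid, u, v in edges if u in positions and v in positions}
    return LayoutResult(positions=positions, routes=routes)


# -- KEGG fixed-position ----------------------------------------------------

def layout_kegg(
    nodes: dict[str, tuple[float, float]],
    edges: Sequence[tuple[str, str, str]],
    hints,
    reaction_edge_ids: Optional[set[str]] = None,
    seed: int = 0,
) -> LayoutResult:
    """Imitate a KEGG map: hinted nodes keep their KGML coordinates verbatim.

    Un-hinted nodes are placed by the force engine and squeezed into the
    hinted bounding box.  Routes are straight segments unless the segment
    crosses a third node's body — then a two-bend orthogonal route is tried.
    Reaction edges are rendered as quadratic curves.
    """
    hinted = {n for n in nodes if n in hints}
    if not hinted:
        logging.getLogger(__name__).warning(
            "KEGG layout: no position hints at all; falling back to force layout")
        return layout_force(nodes, edges, seed=seed)

    positions: dict[str, tuple[float, float, float, float]] = {}
    for n in sorted(hinted):
        x, y, w, h = hints.positions[n]
        positions[n] = (float(x), float(y), float(w), float(h))

    free = sorted(set(nodes) - hinted)
    if free:
        sub = layout_force({n: nodes[n] for n in free},
                           [(e, u, v) for e, u, v in edges
                            if u in free and v in free], seed=seed)
        xs = [p[0] for p in positions.values()]
        ys = [p[1] for p in positions.values()]
        x0, x1 = min(xs), max(xs)
        y0, y1 = min(ys), max(ys)
        fxs = [sub.positions[n][0] for n in free]
        fys = [sub.positions[n][1] for n in free]
        fx0, fx1 = min(fxs), max(fxs)
        fy0, fy1 = min(fys), max(fys)
        for n in free:
            fx, fy, _, _ = sub.positions[n]
            tx = x0 + (fx - fx0) / (fx1 - fx0 or 1) * (x1 - x0 or 1)
            ty = y0 + (fy - fy0) / (fy1 - fy0 or 1) * (y1 - y0 or 1)
            w, h = nodes[n]
            positions[n] = (tx, ty, w, h)
        _separate_overlaps(positions, protected=hinted)

    reaction_edge_ids = reaction_edge_ids or set()
    routes: dict[str, tuple[str, list[tuple[float, float]]]] = {}
    rects = {n: _rect(positions[n]) for n in positions}
    for eid, u, v in edges:
        if u not in positions or v not in positions:
            continue
        p, q = _center(positions[u]), _center(positions[v])
        if eid in reaction_edge_ids:
            routes[eid] = ("quadratic", [p, _quad_control(p, q), q])
            continue
        obstacles = [rects[n] for n in positions if n not in (u, v)]
        if not _segment_hits_any(p, q, obstacles):
            routes[eid] = ("straight", [p, q])
            continue
        route = _orthogonal_route(p, q, obstacles)
        routes[eid] = route if route else ("straight", [p, q])
    return LayoutResult(positions=positions, routes=routes)


# -- geometry helpers -------------------------------------------------------

def _center(pos: tuple[float, float, float, float]) -> tuple[float, float]:
    return (pos[0], pos[1])


def _rect(pos: tuple[float, float, float, float]):
    x, y, w, h = pos
    return (x - w / 2, y - h / 2, x + w / 2, y + h / 2)


def _quad_control(p, q, bulge: float = 0.18) -> tuple[float, float]:
    mx, my = (p[0] + q[0]) / 2, (p[1] + q[1]) / 2
    dx, dy = q[0] - p[0], q[1] - p[1]
    return (mx - dy * bulge, my + dx * bulge)


def _segment_hits_rect(p, q, rect, pad: float = 1.0) -> bool:
    x0, y0, x1, y1 = rect
    x0 -= pad; y0 -= pad; x1 += pad; y1 += pad
    # Liang–Barsky clipping
    dx, dy = q[0] - p[0], q[1] - p[1]
    t0, t1 = 0.0, 1.0
    for num, den in (
        (x0 - p[0], dx), (p[0] - x1, -dx),
        (y0 - p[1], dy), (p[1] - y1, -dy),
    ):
        if den == 0:
            if num > 0:
                return False
            continue
        t = num / den
        if den > 0:
            t0 = max(t0, t)
        else:
            t1 = min(t1, t)
        if t0 > t1:
            return False
    return True


def _segment_hits_any(p, q, rects) -> bool:
    return any(_segment_hits_rect(p, q, r) for r in rects)


def _orthogonal_route(p, q, obstacles):
    """Two-bend orthogonal routes tried in a deterministic order."""
    candidates = []
    mx, my = (p[0] + q[0]) / 2, (p[1] + q[1]) / 2
    for shift in (0.0, 30.0, -30.0, 60.0, -60.0):
        candidates.append([p, (mx + shift, p[1]), (mx + shift, q[1]), q])  # H-V-H
        candidates.append([p, (p[0], my + shift), (q[0], my + shift), q])  # V-H-V
    for pts in candidates:
        ok = all(not _segment_hits_any(a, b, obstacles)
                 for a, b in zip(pts, pts[1:]))
        if ok:
            return ("orthogonal", pts)
    return None


def _separate_overlaps(
    positions: dict[str, tuple[float, float, float, float]],
    protected: Optional[set[str]] = None,
    same_row_only: bool = False,
    gap: float = 6.0,
    max_rounds: int = 50,
) -> None:
    """Push overlapping node bodies apart (deterministic, id-ordered).

    Nodes in ``protected`` never move (KGML hints are kept verbatim).  With
    ``same_row_only`` separation is horizontal only, preserving band y's.
    """
    protected = protected or set()
    ids = sorted(positions)
    for _ in range(max_rounds):
        moved = False
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ax, ay, aw, ah = positions[a]
                bx, by, bw, bh = positions[b]
                ox = (aw + bw) / 2 + gap - abs(ax - bx)
                oy = (ah + bh) / 2 + gap - abs(ay - by)
                if ox <= 0 or oy <= 0:
                    continue
                moved = True
                if same_row_only or ox <= oy:
                    push = ox / 2 + 0.5
                    direction = 1.0 if bx >= ax else -1.0
                    if a in protected and b in protected:
                        continue
                    if a in protected:
                        positions[b] = (bx + direction * 2 * push, by, bw, bh)
                    elif b in protected:
                        positions[a] = (ax - direction * 2 * push, ay, aw, ah)
                    else:
                        positions[a] = (ax - direction * push, ay, aw, ah)
                        positions[b] = (bx + direction * push, by, bw, bh)
                else:
                    push = oy / 2 + 0.5
                    direction = 1.0 if by >= ay else -1.0
                    if a in protected and b in protected:
                        continue
                    if a in protected:
                        positions[b] = (bx, by + direction * 2 * push, bw, bh)
                    elif b in protected:
                        positions[a] = (ax, ay - direction * 2 * push, aw, ah)
                    else:
                        positions[a] = (ax, ay - direction * push, aw, ah)
                        positions[b] = (bx, by + direction * push, bw, bh)
        if not moved:
            return


ENGINES = ("force", "layered", "kegg")
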