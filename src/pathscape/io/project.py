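"""Versioned JSON project format.

A saved project is self-contained: components, hierarchy, collapse state,
all property layers, loaded data series, projection specs and node geometry
round-trip losslessly.  A schema-version mismatch raises an explicit error
naming both versions.
"""

from __future__ import annotations

import json
import math
from typing import Any, Optional

import numpy as np

from ..errors import FormatError, SchemaVersionError
from ..model import (
    AliasInstance, Edge, Entity, Group, NetworkModel, PropertyLayer,
    ReactionHyperedge, Scope,
)
from ..projection import (
    ColorScale, GlyphSpec, ProjectionSpec, SizeScale, Threshold,
)
from ..series import DataSeries

SCHEMA_NAME = "pathscape-project"
SCHEMA_VERSION = 1


def _encode_value(v: Any) -> Any:
    if isinstance(v, tuple):
        return {"__tuple__": [_encode_value(x) for x in v]}
    if isinstance(v, GlyphSpec):
        return {"__glyph__": {"kind": v.kind, "group_names": v.group_names,
                              "values": v.values}}
    if isinstance(v, float) and math.isnan(v):
        return {"__nan__": True}
    return v


def _decode_value(v: Any) -> Any:
    if isinstance(v, dict):
        if "__tuple__" in v:
            return tuple(_decode_value(x) for x in v["__tuple__"])
        if "__glyph__" in v:
            return GlyphSpec(**v["__glyph__"])
        if "__nan__" in v:
            return float("nan")
    return v


def _scale_to_dict(scale: Any) -> Optional[dict]:
    if scale is None:
        return None
    if isinstance(scale, ColorScale):
        return {"type": "color", "domain": list(scale.domain),
                "range": list(scale.range)}
    if isinstance(scale, SizeScale):
        return {"type": "size", "domain": list(scale.domain),
                "size_range": list(scale.size_range)}
    if isinstance(scale, Threshold):
        return {"type": "threshold", "op": scale.op, "cutoff": scale.cutoff,
                "absolute": scale.absolute}
    raise FormatError(f"unserializable scale {type(scale).__name__}")


def _scale_from_dict(data: Optional[dict]) -> Any:
    if data is None:
        return None
    t = data["type"]
    if t == "color":
        return ColorScale(domain=tuple(data["domain"]), range=tuple(data["range"]))
    if t == "size":
        return SizeScale(domain=tuple(data["domain"]),
                         size_range=tuple(data["size_range"]))
    if t == "threshold":
        return Threshold(op=data["op"], cutoff=data["cutoff"],
                         absolute=data["absolute"])
    raise FormatError(f"unknown scale type {t!r}")


def _series_to_dict(s: DataSeries) -> dict:
    matrix = [[None if math.isnan(v) else v for v in row] for row in s.matrix]
    return {
        "name": s.name,
        "row_ids": [sorted(ids) for ids in s.row_ids],
        "samples": list(s.samples),
        "matrix": matrix,
        "groups": {k: list(v) for k, v in s.groups.items()},
        "annotations": dict(s.annotations),
        "duplicate_rows": list(s.duplicate_rows),
    }


def _series_from_dict(d: dict) -> DataSeries:
    matrix = np.array(
        [[math.nan if v is None else float(v) for v in row] for row in d["matrix"]],
        dtype=float,
    ).reshape(len(d["row_ids"]), len(d["samples"]))
    return DataSeries(
        name=d["name"],
        row_ids=[frozenset(ids) for ids in d["row_ids"]],
        samples=list(d["samples"]),
        matrix=matrix,
        groups={k: list(v) for k, v in d.get("groups", {}).items()},
        annotations=dict(d.get("annotations", {})),
        duplicate_rows=list(d.get("duplicate_rows", [])),
    )


def write_project(
    model: NetworkModel,
    series: Optional[list[DataSeries]] = None,
    projections: Optional[list[ProjectionSpec]] = None,
    geometry: Optional[dict[str, tuple]] = None,
) -> str:
    doc = {
        "schema": SCHEMA_NAME,
        "version": SCHEMA_VERSION,
        "model": {
            "name": model.name,
            "entities": [
                {"id": e.id, "kind": e.kind.value, "label": e.label,
                 "xrefs": sorted(map(list, e.xrefs)),
                 "compartments": list(e.compartments)}
                for e in (model.entities[i] for i in sorted(model.entities))
            ],
            "groups": [
                {"id": g.id, "member_ids": list(g.member_ids),
                 "semantics": g.semantics.value, "collapsed": g.collapsed,
                 "own_layout": g.own_layout, "hub_id": g.hub_id,
                 "label": g.label}
                for g in (model.groups[i] for i in sorted(model.groups))
            ],
            "reactions": [
                {"id": r.id, "substrates": [list(s) for s in r.substrates],
                 "products": [list(p) for p in r.products],
                 "catalysts": list(r.catalysts), "cofactors": list(r.cofactors),
                 "reversible": r.reversible, "label": r.label}
                for r in (model.reactions[i] for i in sorted(model.reactions))
            ],
            "edges": [
                {"id": e.id, "source": e.source, "target": e.target,
                 "relation": e.relation.value, "directed": e.directed,
                 "multiplicity": e.multiplicity}
                for e in (model.edges[i] for i in sorted(model.edges))
            ],
            "aliases": [
                {"id": a.id, "entity_id": a.entity_id, "context_id": a.context_id}
                for a in (model.aliases[i] for i in sorted(model.aliases))
            ],
            "id_counter": model._id_counter,
            "layers": {
                scope.value: {
                    cid: {p: _encode_value(v) for p, v in props.items()}
                    for cid, props in sorted(layer.assignments.items())
                }
                for scope, layer in model.layers.items()
            },
        },
        "series": [_series_to_dict(s) for s in (series or [])],
        "projections": [
            {"series_name": p.series_name, "samples": list(p.samples),
             "formula": p.formula, "target": p.target,
             "scale": _scale_to_dict(p.scale),
             "missing_policy": p.missing_policy,
             "neutral_color": p.neutral_color, "glyph_kind": p.glyph_kind,
             "glyph_groups": list(p.glyph_groups)}
            for p in (projections or [])
        ],
        "geometry": {k: list(v) for k, v in (geometry or {}).items()},
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def read_project(text: str) -> tuple[
    NetworkModel, list[DataSeries], list[ProjectionSpec], dict[str, tuple]
]:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"unparsable project JSON: {exc}") from exc
    if doc.get("schema") != SCHEMA_NAME:
        raise FormatError(f"not a {SCHEMA_NAME} document")
    if doc.get("version") != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"project schema version {doc.get('version')!r} is not the "
            f"supported version {SCHEMA_VERSION}")

    m = doc["model"]
    model = NetworkModel(name=m.get("name", "model"))
    for ent in m.get("entities", []):
        model.add_entity(Entity(
            ent["id"], kind=ent["kind"], label=ent.get("label", ""),
            xrefs={tuple(x) for x in ent.get("xrefs", [])},
            compartments=list(ent.get("compartments", [])),
        ))
    for al in m.get("aliases", []):
        model.aliases[al["id"]] = AliasInstance(
            al["id"], al["entity_id"], al.get("context_id"))
    for grp in m.get("groups", []):
        model.add_group(Group(
            grp["id"], member_ids=list(grp["member_ids"]),
            semantics=grp["semantics"], collapsed=grp["collapsed"],
            own_layout=grp.get("own_layout"), hub_id=grp.get("hub_id"),
            label=grp.get("label", ""),
        ))
    for rxn in m.get("reactions", []):
        model.add_reaction(ReactionHyperedge(
            rxn["id"],
            substrates=[(s[0], float(s[1])) for s in rxn["substrates"]],
            products=[(p[0], float(p[1])) for p in rxn["products"]],
            catalysts=list(rxn.get("catalysts", [])),
            cofactors=list(rxn.get("cofactors", [])),
            reversible=rxn.get("reversible", False),
            label=rxn.get("label", ""),
        ))
    for edge in m.get("edges", []):
        model.add_edge(Edge(
            edge["id"], edge["source"], edge["target"],
            relation=edge["relation"], directed=edge["directed"],
            multiplicity=edge.get("multiplicity", 1),
        ))
    model._id_counter = int(m.get("id_counter", 0))
    for scope_name, assignments in m.get("layers", {}).items():
        layer = PropertyLayer(Scope(scope_name))
        for cid, props in assignments.items():
            for p, v in props.items():
                layer.set(cid, p, _decode_value(v))
        model.layers[Scope(scope_name)] = layer
    model.clear_dirty()

    series = [_series_from_dict(d) for d in doc.get("series", [])]
    projections = [
        ProjectionSpec(
            series_name=p["series_name"], samples=list(p.get("samples", [])),
            formula=p.get("formula"), target=p["target"],
            scale=_scale_from_dict(p.get("scale")),
            missing_policy=p.get("missing_policy", "default_appearance"),
            neutral_color=p.get("neutral_color", "#C0C0C0"),
            glyph_kind=p.get("glyph_kind", "bar"),
            glyph_groups=list(p.get("glyph_groups", [])),
        )
        for p in doc.get("projections", [])
    ]
    geometry = {k: tuple(v) for k, v in doc.get("geometry", {}).items()}
    return model, series, projections, geometry
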