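"""Three-step pipeline, incremental updates, and SVG emission."""

import copy
import random

import pytest
from lxml import etree

from pathscape.errors import StateError
from pathscape.model import (
    Edge, Entity, Group, Kind, NetworkModel, Relation, Scope,
)
from pathscape.projection import GlyphSpec
from pathscape.rendering import (
    RenderGraph, apply_layout, assign_attributes, build_topology, full_render,
    incremental_update, render_svg,
)

SVG_NS = "{http://www.w3.org/2000/svg}"


class TestBuildTopology:
    def test_expanded_reaction_is_bipartite(self):
        m = NetworkModel()
        for eid, kind in (("s1", Kind.COMPOUND), ("s2", Kind.COMPOUND),
                          ("p1", Kind.COMPOUND), ("enz", Kind.PROTEIN)):
            m.add_entity(Entity(eid, kind=kind))
        from pathscape.model import ReactionHyperedge
        m.add_reaction(ReactionHyperedge(
            "r", substrates=[("s1", 1), ("s2", 1)], products=[("p1", 1)],
            catalysts=["enz"]))
        rg = build_topology(m)
        assert len(rg.nodes) == 5  # 3 metabolites + reaction + enzyme
        assert len(rg.edges) == 4  # 2 substrate + 1 product + 1 catalysis
        kinds = sorted(e.kind for e in rg.edges.values())
        assert kinds == ["catalysis", "reaction_prod", "reaction_sub",
                         "reaction_sub"]

    def test_empty_model_empty_graph(self):
        rg = build_topology(NetworkModel())
        assert rg.nodes == {} and rg.edges == {}

    def test_invisible_component_and_its_edges_omitted(self, group_model):
        group_model.set_property("N", "visible", False)
        rg = build_topology(group_model)
        assert "N" not in rg.nodes
        assert rg.edges == {}

    def test_reversed_reaction_direction_swaps_edges(self, reaction_model):
        m = reaction_model
        m.reactions["rxn1"].reversible = True
        m.set_property("rxn1", "direction", "reverse", scope=Scope.PROJECTION)
        rg = build_topology(m)
        assert rg.edges["rxn1:sub:glucose"].source == "rxn1"
        assert rg.edges["rxn1:prod:g6p"].target == "rxn1"


class TestAssignAttributes:
    def test_style_reaches_all_render_nodes(self, group_model):
        group_model.apply_style({"protein": {"fill_color": "#AABBCC"}})
        rg = build_topology(group_model)
        assign_attributes(rg, group_model)
        assert all(n.props["fill_color"] == "#AABBCC"
                   for n in rg.nodes.values())

    def test_projection_color_wins_over_style(self, group_model):
        group_model.apply_style({"protein": {"fill_color": "#AABBCC"}})
        group_model.set_property("A", "fill_color", "#FF0000",
                                 scope=Scope.PROJECTION)
        rg = assign_attributes(build_topology(group_model), group_model)
        assert rg.nodes["A"].props["fill_color"] == "#FF0000"
        assert rg.nodes["B"].props["fill_color"] == "#AABBCC"

    def test_defaults_when_no_layers(self):
        m = NetworkModel()
        m.add_entity(Entity("x"))
        rg = assign_attributes(build_topology(m), m)
        assert rg.nodes["x"].props["fill_color"] == "#FFFFFF"
        assert rg.nodes["x"].props["visible"] is True

    def test_step_order_enforced(self):
        with pytest.raises(StateError):
            assign_attributes(RenderGraph(), NetworkModel())

    def test_attributes_never_alter_topology(self, group_model):
        rg = build_topology(group_model)
        nodes_before = set(rg.nodes)
        edges_before = {(e.source, e.target) for e in rg.edges.values()}
        assign_attributes(rg, group_model)
        assert set(rg.nodes) == nodes_before
        assert {(e.source, e.target) for e in rg.edges.values()} == edges_before


class TestApplyLayout:
    def test_single_node_finite_coords(self):
        m = NetworkModel()
        m.add_entity(Entity("x"))
        rg = full_render(m, "force", {"seed": 1})
        assert rg.nodes["x"].geometry is not None

    def test_rerender_is_deterministic(self, regulatory_model):
        rg1 = full_render(regulatory_model, "force", {"seed": 5})
        rg2 = full_render(regulatory_model, "force", {"seed": 5})
        assert rg1 == rg2

    def test_layout_never_alters_attributes(self, group_model):
        rg = assign_attributes(build_topology(group_model), group_model)
        props_before = {nid: dict(n.props) for nid, n in rg.nodes.items()}
        apply_layout(rg, group_model, "force", {"seed": 0})
        assert {nid: n.props for nid, n in rg.nodes.items()} == props_before

    def test_unknown_engine_rejected(self, group_model):
        from pathscape.errors import ConfigError
        rg = assign_attributes(build_topology(group_model), group_model)
        with pytest.raises(ConfigError):
            apply_layout(rg, group_model, "banana")

    def test_own_layout_group_obeys_local_bands(self):
        m = NetworkModel()
        for eid, comp in (("rec", "plasma_membrane"), ("kin", "cytoplasm"),
                          ("tf", "nucleus"), ("outside", "cytoplasm")):
            m.add_entity(Entity(eid, compartments=[comp]))
        m.add_edge(Edge("e1", "rec", "kin"))
        m.add_edge(Edge("e2", "kin", "tf"))
        m.add_group(Group("cascade", member_ids=["rec", "kin", "tf"],
                          own_layout="layered"))
        rg = full_render(m, "force", {"seed": 2})
        ys = {n: rg.nodes[n].geometry[1] for n in ("rec", "kin", "tf")}
        assert ys["rec"] < ys["kin"] < ys["tf"]


class _EditScript:
    """Random model edits used to compare incremental vs full rendering."""

    def __init__(self, rng: random.Random):
        self.rng = rng

    def apply(self, model: NetworkModel) -> None:
        ops = [self.toggle_collapse, self.set_fill, self.set_visibility,
               self.set_size, self.set_label]
        for _ in range(self.rng.randrange(1, 4)):
            self.rng.choice(ops)(model)

    def _component(self, model):
        pool = sorted(model.entities) + sorted(model.groups)
        return self.rng.choice(pool)

    def toggle_collapse(self, model):
        if not model.groups:
            return
        gid = self.rng.choice(sorted(model.groups))
        if model.groups[gid].collapsed:
            model.expand_group(gid)
        else:
            model.collapse_group(gid)

    def set_fill(self, model):
        color = "#%06X" % self.rng.randrange(0xFFFFFF)
        scope = self.rng.choice([Scope.STYLE, Scope.USER_OVERRIDE,
                                 Scope.PROJECTION])
        model.set_property(self._component(model), "fill_color", color, scope)

    def set_visibility(self, model):
        model.set_property(self._component(model), "visible",
                           self.rng.random() < 0.7)

    def set_size(self, model):
        size = (float(self.rng.randrange(20, 80)),
                float(self.rng.randrange(12, 40)))
        model.set_property(self._component(model), "size", size)

    def set_label(self, model):
        model.set_property(self._component(model), "label",
                           f"L{self.rng.randrange(100)}")


def _random_model(rng: random.Random) -> NetworkModel:
    m = NetworkModel()
    n = rng.randrange(5, 12)
    for i in range(n):
        m.add_entity(Entity(f"n{i}", kind=rng.choice(list(Kind))))
    for i in range(rng.randrange(3, 10)):
        a, b = rng.sample(range(n), 2)
        m.add_edge(Edge(f"e{i}", f"n{a}", f"n{b}",
                        relation=rng.choice(list(Relation))))
    if rng.random() < 0.8:
        members = [f"n{i}" for i in sorted(rng.sample(range(n), 3))]
        m.add_group(Group("grp", member_ids=members))
    m.clear_dirty()
    return m


class TestIncrementalUpdate:
    N_SCRIPTS = 250  # the full-scale sweep runs in the acceptance harness

    def test_incremental_equals_full_rebuild_on_random_edit_scripts(self):
        rng = random.Random(20240101)
        for case in range(self.N_SCRIPTS):
            model = _random_model(rng)
            rg = full_render(model, "force", {"seed": 11})
            _EditScript(rng).apply(model)
            rg = incremental_update(model, rg)
            fresh = full_render(
                copy.deepcopy(model), "force", {"seed": 11})
            assert rg == fresh, f"divergence in case {case}"

    def test_visual_only_change_skips_topology_step(self, group_model):
        rg = full_render(group_model, "force", {"seed": 0})
        stamp = rg.step_stamps["topology"]
        group_model.set_property("A", "fill_color", "#123456")
        rg = incremental_update(group_model, rg)
        assert rg.step_stamps["topology"] == stamp
        fresh = full_render(copy.deepcopy(group_model), "force", {"seed": 0})
        assert rg == fresh

    def test_collapse_triggers_full_equivalence(self, group_model):
        rg = full_render(group_model, "force", {"seed": 0})
        group_model.collapse_group("G")
        rg = incremental_update(group_model, rg)
        fresh = full_render(copy.deepcopy(group_model), "force", {"seed": 0})
        assert rg == fresh

    def test_no_dirt_returns_graph_unchanged(self, group_model):
        rg = full_render(group_model, "force", {"seed": 0})
        assert incremental_update(group_model, rg) is rg

    def test_dirty_flags_cleared_after_render(self, group_model):
        group_model.set_property("A", "fill_color", "#101010")
        rg = full_render(group_model, "force", {"seed": 0})
        assert group_model.dirty == {}
        group_model.set_property("A", "fill_color", "#202020")
        incremental_update(group_model, rg)
        assert group_model.dirty == {}


class TestRenderSvg:
    def _svg_root(self, text):
        return etree.fromstring(text.encode())

    def test_red_node_appears_with_fill(self):
        m = NetworkModel()
        m.add_entity(Entity("x"))
        m.set_property("x", "fill_color", "#FF0000")
        svg = render_svg(full_render(m, "force", {"seed": 0}))
        root = self._svg_root(svg)
        assert root.tag == f"{SVG_NS}svg"
        fills = [el.get("fill") for el in root.iter()
                 if el.get("fill") == "#FF0000"]
        assert fills

    def test_reaction_edges_use_quadratic_commands(self, reaction_model):
        svg = render_svg(full_render(reaction_model, "force", {"seed": 0}))
        root = self._svg_root(svg)
        quads = [el for el in root.iter(f"{SVG_NS}path")
                 if " Q " in el.get("d", "")]
        assert len(quads) >= 3  # substrate, product, co-factor arrows

    def test_empty_graph_is_valid_svg(self):
        svg = render_svg(full_render(NetworkModel(), "force", {"seed": 0}))
        root = self._svg_root(svg)
        shapes = [el for el in root.iter()
                  if el.tag in (f"{SVG_NS}ellipse", f"{SVG_NS}rect",
                                f"{SVG_NS}polygon")]
        assert shapes == []

    def test_unlaid_out_graph_is_a_state_error(self, group_model):
        rg = assign_attributes(build_topology(group_model), group_model)
        with pytest.raises(StateError):
            render_svg(rg)

    def test_aggregate_multiplicity_rendered_as_label(self, group_model):
        group_model.collapse_group("G")
        svg = render_svg(full_render(group_model, "force", {"seed": 0}))
        assert ">x3</text>" in svg

    def test_compartment_bands_drawn_for_layered(self, regulatory_model):
        svg = render_svg(full_render(regulatory_model, "layered", {"seed": 0}))
        assert "nucleus" in svg and "plasma_membrane" in svg

    def test_glyph_node_renders_mini_chart(self):
        m = NetworkModel()
        m.add_entity(Entity("x"))
        m.set_property("x", "shape",
                       GlyphSpec("bar", ["t0", "t1"], [1.0, 2.0]),
                       scope=Scope.PROJECTION)
        svg = render_svg(full_render(m, "force", {"seed": 0}))
        assert 'class="glyph"' in svg

    def test_byte_identical_for_fixed_seed(self, regulatory_model):
        svg1 = render_svg(full_render(regulatory_model, "layered", {"seed": 3}))
        svg2 = render_svg(full_render(regulatory_model, "layered", {"seed": 3}))
        assert svg1 == svg2
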