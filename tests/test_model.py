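"""Hierarchical model: collapse/expand, aliasing, neighborhoods, properties."""

import pytest
from hypothesis import given, settings, strategies as st

from pathscape.errors import ConfigError, NotFoundError
from pathscape.model import (
    Edge, Entity, Group, GroupSemantics, Kind, NetworkModel, PROPERTY_DEFAULTS,
    Relation, Scope,
)
from pathscape.rendering import build_topology


def render_topology_signature(model):
    rg = build_topology(model)
    return (
        frozenset(rg.nodes),
        frozenset((e.source, e.target, e.relation, e.multiplicity)
                  for e in rg.edges.values()),
    )


class TestCollapseExpand:
    def test_collapse_aggregates_parallel_external_edges(self, group_model):
        group_model.collapse_group("G")
        rg = build_topology(group_model)
        assert set(rg.nodes) == {"G", "N"}
        assert len(rg.edges) == 1
        (edge,) = rg.edges.values()
        assert edge.multiplicity == 3
        assert edge.kind == "aggregate"
        assert edge.relation == "activation"  # uniform member relations survive

    def test_mixed_relations_aggregate_to_generic(self, group_model):
        group_model.edges["e1"].relation = Relation.INHIBITION
        group_model.collapse_group("G")
        (edge,) = build_topology(group_model).edges.values()
        assert edge.relation == "generic"

    def test_collapse_without_external_edges(self):
        m = NetworkModel()
        for eid in ("A", "B"):
            m.add_entity(Entity(eid))
        m.add_group(Group("G", member_ids=["A", "B"]))
        m.add_edge(Edge("internal", "A", "B"))
        m.collapse_group("G")
        rg = build_topology(m)
        assert set(rg.nodes) == {"G"}
        assert rg.edges == {}

    def test_collapse_expand_round_trip_restores_topology(self, group_model):
        before = render_topology_signature(group_model)
        group_model.collapse_group("G")
        group_model.expand_group("G")
        assert render_topology_signature(group_model) == before

    def test_collapse_is_idempotent_and_expand_noop(self, group_model):
        group_model.collapse_group("G")
        sig = render_topology_signature(group_model)
        group_model.collapse_group("G")  # no-op
        assert render_topology_signature(group_model) == sig
        group_model.expand_group("G")
        group_model.expand_group("G")  # no-op

    def test_unknown_group_raises(self, group_model):
        with pytest.raises(NotFoundError):
            group_model.collapse_group("nope")
        with pytest.raises(NotFoundError):
            group_model.expand_group("nope")

    def test_aggregate_multiplicity_conserves_external_edge_count(self, group_model):
        group_model.add_entity(Entity("M"))
        group_model.add_edge(Edge("e3", "A", "M"))
        group_model.add_edge(Edge("e4", "M", "B"))
        group_model.collapse_group("G")
        rg = build_topology(group_model)
        total = sum(e.multiplicity for e in rg.edges.values()
                    if "G" in (e.source, e.target))
        assert total == 5  # e0..e2 to N, e3 to M, e4 from M

    def test_collapsed_cofactor_group_hides_members(self, reaction_model):
        m = reaction_model
        m.add_group(Group("cof", member_ids=["atp"],
                          semantics=GroupSemantics.REACTION_COFACTORS,
                          collapsed=True))
        rg = build_topology(m)
        assert "atp" not in rg.nodes
        assert "cof" not in rg.nodes  # hidden, not aggregated
        assert "rxn1:sub:atp" not in rg.edges
        m.expand_group("cof")
        rg = build_topology(m)
        assert "atp" in rg.nodes  # reopened co-factors rejoin the drawing
        assert "rxn1:sub:atp" in rg.edges


class TestAliasing:
    def test_alias_into_two_contexts(self):
        m = NetworkModel()
        m.add_entity(Entity("ATP", kind=Kind.COMPOUND))
        for gid in ("path1", "path2"):
            m.add_entity(Entity(f"{gid}_anchor"))
            m.add_group(Group(gid, member_ids=[f"{gid}_anchor"],
                              semantics=GroupSemantics.PATHWAY))
        i1 = m.create_alias("ATP", "path1")
        i2 = m.create_alias("ATP", "path2")
        assert len(m.instances_of("ATP")) == 2  # two instances, one entity
        assert list(m.entities).count("ATP") == 1
        assert m.highlight_instances("ATP") == sorted([i1, i2])
        rg = build_topology(m)
        assert i1 in rg.nodes and i2 in rg.nodes and "ATP" not in rg.nodes

    def test_merge_unions_disjoint_edge_sets(self):
        m = NetworkModel()
        for eid in ("E", "X", "Y"):
            m.add_entity(Entity(eid))
        i1 = m.create_alias("E", None)
        i2 = m.create_alias("E", None)
        m.add_edge(Edge("ex", i1, "X"))
        m.add_edge(Edge("ey", i2, "Y"))
        m.merge_aliases("E")
        assert len(m.instances_of("E")) == 1
        (keep,) = m.instances_of("E")
        assert {(e.source, e.target) for e in m.edges.values()} == {
            (keep, "X"), (keep, "Y")}

    def test_merge_collapses_identical_edges_with_multiplicity(self):
        m = NetworkModel()
        for eid in ("E", "X"):
            m.add_entity(Entity(eid))
        i1 = m.create_alias("E", None)
        i2 = m.create_alias("E", None)
        m.add_edge(Edge("a", i1, "X"))
        m.add_edge(Edge("b", i2, "X"))
        m.merge_aliases("E")
        (edge,) = m.edges.values()
        assert edge.multiplicity == 2

    def test_merge_single_instance_is_noop(self):
        m = NetworkModel()
        m.add_entity(Entity("E"))
        m.create_alias("E", None)
        before = len(m.aliases)
        m.merge_aliases("E")
        assert len(m.aliases) == before

    def test_alias_unknown_entity_raises(self):
        with pytest.raises(NotFoundError):
            NetworkModel().create_alias("ghost", None)

    def test_alias_conservation_after_merging_everything(self):
        m = NetworkModel()
        for eid in ("A", "B"):
            m.add_entity(Entity(eid))
        for _ in range(3):
            m.create_alias("A", None)
        m.create_alias("B", None)
        for eid in list(m.entities):
            m.merge_aliases(eid)
        assert set(m.entities) == {"A", "B"}
        assert all(len(m.instances_of(e)) <= 1 for e in m.entities)


class TestNeighborhood:
    @pytest.fixture
    def source_net(self):
        src = NetworkModel("reference")
        for eid in ("hub", "in1", "in2", "out1", "out2", "out3"):
            src.add_entity(Entity(eid))
        src.add_edge(Edge("i1", "in1", "hub"))
        src.add_edge(Edge("i2", "in2", "hub"))
        for i, tgt in enumerate(("out1", "out2", "out3")):
            src.add_edge(Edge(f"o{i}", "hub", tgt))
        return src

    def test_upstream_pulls_only_in_edges(self, source_net):
        m = NetworkModel()
        m.add_entity(Entity("hub"))
        m.expand_neighborhood("hub", "upstream", source_net)
        assert len(m.edges) == 2
        assert set(m.entities) == {"hub", "in1", "in2"}

    def test_downstream_and_both(self, source_net):
        m = NetworkModel()
        m.add_entity(Entity("hub"))
        m.expand_neighborhood("hub", "downstream", source_net)
        assert len(m.edges) == 3
        m.expand_neighborhood("hub", "both", source_net)
        assert len(m.edges) == 5

    def test_expansion_is_idempotent(self, source_net):
        m = NetworkModel()
        m.add_entity(Entity("hub"))
        m.expand_neighborhood("hub", "both", source_net)
        n_e, n_v = len(m.edges), len(m.entities)
        m.expand_neighborhood("hub", "both", source_net)
        assert (len(m.edges), len(m.entities)) == (n_e, n_v)

    def test_isolated_node_expands_to_nothing(self, source_net):
        m = NetworkModel()
        m.add_entity(Entity("loner"))
        src = NetworkModel()
        src.add_entity(Entity("loner"))
        m.expand_neighborhood("loner", "both", src)
        assert len(m.edges) == 0

    def test_entity_absent_from_source_warns_not_raises(self, source_net, caplog):
        m = NetworkModel()
        m.add_entity(Entity("orphan"))
        with caplog.at_level("WARNING"):
            m.expand_neighborhood("orphan", "both", source_net)
        assert len(m.edges) == 0
        assert any("absent" in r.message for r in caplog.records)


class TestPropertyResolution:
    def test_defaults_without_any_layer(self):
        m = NetworkModel()
        m.add_entity(Entity("A", kind=Kind.COMPOUND))
        assert m.resolve_property("A", "fill_color") == "#FFFFFF"
        assert m.resolve_property("A", "shape") == "circle"  # kind default
        assert m.resolve_property("A", "label") == "A"

    def test_override_beats_style(self):
        m = NetworkModel()
        m.add_entity(Entity("A"))
        m.set_property("A", "fill_color", "#111111", scope=Scope.STYLE)
        m.set_property("A", "fill_color", "#222222", scope=Scope.USER_OVERRIDE)
        assert m.resolve_property("A", "fill_color") == "#222222"

    def test_projection_beats_override_and_clearing_restores(self):
        m = NetworkModel()
        m.add_entity(Entity("A"))
        m.set_property("A", "fill_color", "#222222", scope=Scope.USER_OVERRIDE)
        m.set_property("A", "fill_color", "#333333", scope=Scope.PROJECTION)
        assert m.resolve_property("A", "fill_color") == "#333333"
        m.clear_projection_layer()
        assert m.resolve_property("A", "fill_color") == "#222222"

    def test_unknown_property_raises(self):
        m = NetworkModel()
        m.add_entity(Entity("A"))
        with pytest.raises(ConfigError):
            m.resolve_property("A", "sparkle")

    @given(st.sets(st.sampled_from(sorted(PROPERTY_DEFAULTS)), max_size=4),
           st.sampled_from([Scope.STYLE, Scope.USER_OVERRIDE, Scope.PROJECTION]))
    @settings(max_examples=50, deadline=None)
    def test_resolution_is_total(self, assigned, scope):
        """Any (component, property) query yields a value whatever layers hold."""
        m = NetworkModel()
        m.add_entity(Entity("A"))
        for prop in assigned:
            m.layers[scope].set("A", prop, PROPERTY_DEFAULTS[prop])
        for prop in PROPERTY_DEFAULTS:
            assert m.resolve_property("A", prop) is not None

    def test_apply_style_targets_kinds(self):
        m = NetworkModel()
        m.add_entity(Entity("p", kind=Kind.PROTEIN))
        m.add_entity(Entity("c", kind=Kind.COMPOUND))
        m.apply_style({"protein": {"fill_color": "#AABBCC"}})
        assert m.resolve_property("p", "fill_color") == "#AABBCC"
        assert m.resolve_property("c", "fill_color") == "#FFFFFF"


class TestConstruction:
    def test_hierarchy_cycle_rejected(self):
        m = NetworkModel()
        m.add_entity(Entity("x"))
        m.add_group(Group("g1", member_ids=["x"]))
        with pytest.raises(ConfigError):
            m.add_group(Group("g2", member_ids=["g1"]))
            m.groups["g1"].member_ids.append("g2")
            m.parent["g2"] = "g1"
            m._check_acyclic("g2")

    def test_double_parent_rejected(self):
        m = NetworkModel()
        m.add_entity(Entity("x"))
        m.add_group(Group("g1", member_ids=["x"]))
        with pytest.raises(ConfigError):
            m.add_group(Group("g2", member_ids=["x"]))

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigError):
            Group("g", member_ids=[])

    def test_cofactor_must_be_participant(self):
        from pathscape.model import ReactionHyperedge
        with pytest.raises(ConfigError):
            ReactionHyperedge("r", substrates=[("a", 1)], products=[("b", 1)],
                              cofactors=["zzz"])

    def test_edge_referential_integrity(self):
        m = NetworkModel()
        m.add_entity(Entity("a"))
        with pytest.raises(NotFoundError):
            m.add_edge(Edge("e", "a", "ghost"))

    def test_star_group_renders_radial_edges(self):
        m = NetworkModel()
        for eid in ("hub", "s1", "s2"):
            m.add_entity(Entity(eid))
        m.add_star("st", "hub", ["s1", "s2"])
        rg = build_topology(m)
        star_edges = {(e.source, e.target) for e in rg.edges.values()
                      if e.kind == "star"}
        assert star_edges == {("hub", "s1"), ("hub", "s2")}
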