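import numpy as np
import pytest

from pathscape.model import (
    Edge, Entity, Group, GroupSemantics, Kind, NetworkModel, ReactionHyperedge,
    Relation,
)
from pathscape.series import DataSeries


@pytest.fixture
def group_model() -> NetworkModel:
    """Three proteins in one group, each with one edge to the same outside node."""
    m = NetworkModel("group-fixture")
    for eid in ("A", "B", "C", "N"):
        m.add_entity(Entity(eid, kind=Kind.PROTEIN))
    m.add_group(Group("G", member_ids=["A", "B", "C"],
                      semantics=GroupSemantics.COMPLEX))
    for i, src in enumerate(("A", "B", "C")):
        m.add_edge(Edge(f"e{i}", src, "N", relation=Relation.ACTIVATION))
    m.clear_dirty()
    return m


@pytest.fixture
def reaction_model() -> NetworkModel:
    """One reaction: 2 substrates (one an ATP-style co-factor), 1 product,
    1 enzyme catalyst."""
    m = NetworkModel("reaction-fixture")
    for eid, kind in (("glucose", Kind.COMPOUND), ("atp", Kind.COMPOUND),
                      ("g6p", Kind.COMPOUND), ("hexokinase", Kind.PROTEIN)):
        m.add_entity(Entity(eid, kind=kind))
    m.add_reaction(ReactionHyperedge(
        "rxn1",
        substrates=[("glucose", 1.0), ("atp", 1.0)],
        products=[("g6p", 1.0)],
        catalysts=["hexokinase"],
        cofactors=["atp"],
    ))
    m.clear_dirty()
    return m


@pytest.fixture
def regulatory_model() -> NetworkModel:
    from pathscape.fixtures import gen_regulatory_model
    return gen_regulatory_model(30, seed=7)


@pytest.fixture
def small_series() -> DataSeries:
    return DataSeries(
        name="demo",
        row_ids=[frozenset(["P1"]), frozenset(["P2"]), frozenset(["P3"])],
        samples=["control", "treated"],
        matrix=np.array([[2.0, 8.0], [4.0, 4.0], [1.0, np.nan]]),
        groups={"ctl": ["control"], "trt": ["treated"]},
    )
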