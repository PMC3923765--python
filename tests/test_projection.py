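"""Omics projection: mapping, derived samples, scales, glyphs, colors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from pathscape.errors import ConfigError, ExpressionError
from pathscape.io import read_id_mapping
from pathscape.model import Entity, Kind, NetworkModel, Scope
from pathscape.projection import (
    AMBIGUOUS_COLOR, NO_INFO_COLOR, UNAMBIGUOUS_COLOR, ColorScale, GlyphSpec,
    ProjectionSpec, SizeScale, Threshold, compartment_ambiguity_color,
    derive_sample, evaluate_expression, map_rows_to_entities, mean_sample,
    project, project_time_series, register_function,
)
from pathscape.series import DataSeries


def _series(matrix, samples=None, row_ids=None, groups=None):
    matrix = np.asarray(matrix, dtype=float)
    samples = samples or [f"s{i}" for i in range(matrix.shape[1])]
    row_ids = row_ids or [frozenset([f"P{i}"]) for i in range(matrix.shape[0])]
    return DataSeries("t", row_ids, list(samples), matrix, groups=groups or {})


class TestRowMapping:
    @pytest.fixture
    def model(self):
        m = NetworkModel()
        m.add_entity(Entity("node1", xrefs={("uniprot", "P1")}))
        m.add_entity(Entity("P2"))
        return m

    def test_xref_match(self, model):
        s = _series([[1.0]], row_ids=[frozenset(["P1"])])
        assert map_rows_to_entities(s, model) == {0: {"node1"}}

    def test_unmapped_row_reported_not_raised(self, model):
        s = _series([[1.0]], row_ids=[frozenset(["X9"])])
        assert map_rows_to_entities(s, model) == {}

    def test_mapping_table_bridges_identifiers(self, model):
        s = _series([[1.0]], row_ids=[frozenset(["X9"])])
        table = read_id_mapping("X9\tP1\n")
        assert map_rows_to_entities(s, model, table) == {0: {"node1"}}

    def test_row_order_permutation_invariance(self, model):
        rows = [frozenset(["P1"]), frozenset(["P2"]), frozenset(["zz"])]
        s1 = _series([[1], [2], [3]], row_ids=rows)
        s2 = _series([[3], [2], [1]], row_ids=rows[::-1])
        m1 = map_rows_to_entities(s1, model)
        m2 = map_rows_to_entities(s2, model)
        assert {frozenset(v) for v in m1.values()} == \
            {frozenset(v) for v in m2.values()}


class TestMeanSample:
    def test_arithmetic_mean(self):
        s = _series([[2.0, 4.0]])
        assert mean_sample(s, ["s0", "s1"])[0] == 3.0

    def test_missing_values_skipped(self):
        s = _series([[5.0, np.nan]])
        assert mean_sample(s, ["s0", "s1"])[0] == 5.0

    def test_all_missing_row_stays_missing(self):
        s = _series([[np.nan, np.nan]])
        assert math.isnan(mean_sample(s, ["s0", "s1"])[0])

    def test_single_sample_returned_unchanged(self):
        s = _series([[7.0, 1.0]])
        assert mean_sample(s, ["s0"])[0] == 7.0

    def test_mean_of_identical_samples_is_identity(self):
        s = _series([[3.0, 3.0, 3.0]])
        assert mean_sample(s, ["s0", "s1", "s2"])[0] == 3.0


class TestExpressionEvaluator:
    def test_log2_ratio(self):
        s = _series([[8.0, 2.0]], samples=["treated", "control"])
        out = evaluate_expression(s, "log2(treated/control)")
        assert out[0] == 2.0

    def test_malformed_expression_raises(self):
        s = _series([[1.0]], samples=["s1"])
        with pytest.raises(ExpressionError):
            evaluate_expression(s, "s1 -")

    def test_unknown_sample_named_in_error(self):
        s = _series([[1.0]], samples=["s1"])
        with pytest.raises(ExpressionError, match="ghost"):
            evaluate_expression(s, "s1 + ghost")

    def test_unknown_function_named_in_error(self):
        s = _series([[1.0]], samples=["s1"])
        with pytest.raises(ExpressionError, match="frobnicate"):
            evaluate_expression(s, "frobnicate(s1)")

    def test_division_by_zero_yields_missing(self, caplog):
        s = _series([[1.0, 0.0]], samples=["a", "b"])
        with caplog.at_level("WARNING"):
            out = evaluate_expression(s, "a/b")
        assert math.isnan(out[0])
        assert any("division by zero" in r.message for r in caplog.records)

    def test_missing_operand_propagates(self):
        s = _series([[np.nan, 2.0]], samples=["a", "b"])
        assert math.isnan(evaluate_expression(s, "a + b")[0])

    def test_power_is_right_associative(self):
        s = _series([[2.0]], samples=["x"])
        assert evaluate_expression(s, "x ^ 1 ^ 2")[0] == 2.0  # 2^(1^2)

    def test_unary_minus_and_parens(self):
        s = _series([[3.0]], samples=["x"])
        assert evaluate_expression(s, "-(x + 1) * 2")[0] == -8.0

    def test_zscore_matches_scipy(self):
        from scipy import stats
        col = np.array([1.0, 2.0, np.nan, 4.0, 8.0])
        s = _series(col.reshape(-1, 1), samples=["x"])
        out = evaluate_expression(s, "zscore(x)")
        expected = stats.zscore(col, nan_policy="omit")
        np.testing.assert_allclose(out, expected, equal_nan=True)

    def test_derive_appends_named_sample(self):
        s = _series([[8.0, 2.0]], samples=["t", "c"])
        name = derive_sample(s, "log2(t/c)", name="lfc")
        assert name == "lfc"
        assert s.column("lfc")[0] == 2.0

    def test_registered_function_hook(self):
        register_function("double", lambda x: 2 * x)
        s = _series([[3.0]], samples=["x"])
        assert evaluate_expression(s, "double(x)")[0] == 6.0

    @given(arrays(float, (4, 3),
                  elements=st.floats(-50, 50, allow_nan=False) | st.just(np.nan)))
    @settings(max_examples=60, deadline=None)
    def test_mean_function_equals_mean_sample(self, matrix):
        """derive_sample('mean(...)') and mean_sample agree for all inputs."""
        s = _series(matrix)
        via_expr = evaluate_expression(s, "mean(s0, s1, s2)")
        via_op = mean_sample(s, ["s0", "s1", "s2"])
        np.testing.assert_allclose(via_expr, via_op, equal_nan=True)


class TestColorScale:
    def test_anchor_colors_exact(self):
        scale = ColorScale(domain=(-2, 0, 2),
                           range=("#0000FF", "#FFFFFF", "#FF0000"))
        assert scale(-2) == "#0000FF"
        assert scale(0) == "#FFFFFF"
        assert scale(2) == "#FF0000"

    def test_channelwise_midpoint(self):
        scale = ColorScale(domain=(0, 2, 4),
                           range=("#000000", "#404080", "#FFFFFF"))
        assert scale(1) == "#202040"  # midpoint of min and mid per channel

    def test_clamping_outside_domain(self):
        scale = ColorScale()
        assert scale(-99) == scale(scale.domain[0])
        assert scale(99) == scale(scale.domain[2])

    def test_monotone_per_channel(self):
        scale = ColorScale(domain=(-1, 0, 1),
                           range=("#0000FF", "#FFFFFF", "#FF0000"))
        reds = [int(scale(v)[1:3], 16) for v in np.linspace(-1, 1, 21)]
        assert reds == sorted(reds)

    def test_bad_domain_rejected(self):
        with pytest.raises(ConfigError):
            ColorScale(domain=(2, 0, -2))


class TestProject:
    @pytest.fixture
    def model(self):
        m = NetworkModel()
        for eid in ("P0", "P1"):
            m.add_entity(Entity(eid))
        return m

    def test_fill_color_from_scale(self, model):
        s = _series([[-2.0], [2.0]])
        spec = ProjectionSpec("t", samples=["s0"], target="fill_color",
                              scale=ColorScale(domain=(-2, 0, 2)))
        layer = project(model, s, spec, map_rows_to_entities(s, model))
        assert layer.get("P0", "fill_color") == "#0000FF"
        assert layer.get("P1", "fill_color") == "#FF0000"

    def test_visibility_threshold(self, model):
        s = _series([[0.5], [-2.0]])
        spec = ProjectionSpec("t", samples=["s0"], target="visibility",
                              scale=Threshold(op=">=", cutoff=1.0, absolute=True))
        layer = project(model, s, spec, map_rows_to_entities(s, model))
        assert layer.get("P0", "visible") is False
        assert layer.get("P1", "visible") is True

    def test_multiple_rows_one_entity_averaged(self, model):
        s = _series([[1.0], [3.0]],
                    row_ids=[frozenset(["P0"]), frozenset(["P0"])])
        spec = ProjectionSpec("t", samples=["s0"], target="node_size",
                              scale=SizeScale(domain=(0, 4), size_range=(0, 40)))
        layer = project(model, s, spec, map_rows_to_entities(s, model))
        assert layer.get("P0", "size") == (20.0, 20.0)  # mean(1,3)=2 -> mid

    def test_projection_does_not_mutate_series_or_lower_layers(self, model):
        model.set_property("P0", "fill_color", "#ABCDEF",
                           scope=Scope.USER_OVERRIDE)
        s = _series([[1.0], [2.0]])
        before = s.matrix.copy()
        spec = ProjectionSpec("t", samples=["s0"], target="fill_color")
        project(model, s, spec, map_rows_to_entities(s, model))
        np.testing.assert_array_equal(s.matrix, before)
        assert model.layers[Scope.USER_OVERRIDE].get("P0", "fill_color") \
            == "#ABCDEF"
        model.clear_projection_layer()
        assert model.resolve_property("P0", "fill_color") == "#ABCDEF"

    def test_scale_target_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            ProjectionSpec("t", samples=["s0"], target="fill_color",
                           scale=Threshold())

    def test_missing_policy_hide(self, model):
        s = _series([[1.0]], row_ids=[frozenset(["P0"])])
        spec = ProjectionSpec("t", samples=["s0"], target="fill_color",
                              missing_policy="hide")
        layer = project(model, s, spec, map_rows_to_entities(s, model))
        assert layer.get("P1", "visible") is False


class TestTimeSeriesGlyphs:
    def test_bar_glyph_vector_per_group(self):
        m = NetworkModel()
        m.add_entity(Entity("P0"))
        s = _series([[1.0, 2.0, 3.0]], samples=["t0", "t1", "t2"],
                    groups={"g0": ["t0"], "g1": ["t1"], "g2": ["t2"]})
        layer = project_time_series(m, s, ["g0", "g1", "g2"], "bar",
                                    map_rows_to_entities(s, m))
        glyph = layer.get("P0", "shape")
        assert isinstance(glyph, GlyphSpec)
        assert glyph.values == [1.0, 2.0, 3.0]

    def test_replicates_average_within_group(self):
        m = NetworkModel()
        m.add_entity(Entity("P0"))
        s = _series([[2.0, 4.0]], samples=["r1", "r2"],
                    groups={"g0": ["r1", "r2"]})
        layer = project_time_series(m, s, ["g0"], "bar",
                                    map_rows_to_entities(s, m))
        assert layer.get("P0", "shape").values == [3.0]

    def test_empty_mapping_emits_no_glyphs(self):
        m = NetworkModel()
        m.add_entity(Entity("somebody_else"))
        s = _series([[1.0]], groups={"g0": ["s0"]})
        layer = project_time_series(m, s, ["g0"], "bar", {})
        assert layer.assignments == {}

    def test_glyph_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            GlyphSpec("bar", ["a", "b"], [1.0])


class TestCompartmentColors:
    @pytest.mark.parametrize("compartments,expected", [
        (["nucleus"], UNAMBIGUOUS_COLOR),
        (["nucleus", "cytoplasm"], AMBIGUOUS_COLOR),
        ([], NO_INFO_COLOR),
    ])
    def test_certainty_color_cases(self, compartments, expected):
        e = Entity("x", kind=Kind.PROTEIN, compartments=compartments)
        assert compartment_ambiguity_color(e) == expected
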