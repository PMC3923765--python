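"""Projection of tabular omics values onto network visual attributes.

The framework maps rows of a :class:`~pathscape.series.DataSeries` to model
entities (directly or through an identifier-mapping table), derives temporary
samples (mean of a selection, or a row-wise formula over sample names), and
writes the chosen visual attribute — fill color through a diverging scale,
node size, line width, visibility thresholds, per-node time-series glyphs, or
compartment-ambiguity coloring — into a projection-scope property layer.
The projection layer sits on top of user overrides, so projected data always
shows; removing the layer restores the prior appearance exactly.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Optional, Sequence

import numpy as np

from .errors import ConfigError, ExpressionError
from .model import NetworkModel, PropertyLayer, Scope
from .series import DataSeries

if TYPE_CHECKING:  # pragma: no cover
    from .io.idmap import IdMappingTable

logger = logging.getLogger(__name__)

# -- colors -----------------------------------------------------------------

_HEX = re.compile(r"^#[0-9A-Fa-f]{6}$")

#: Fig-2-style subcellular-location certainty colors (configurable).
UNAMBIGUOUS_COLOR = "#FF0000"   # exactly one annotated compartment: red
AMBIGUOUS_COLOR = "#FFC0CB"     # several compartments: rose
NO_INFO_COLOR = "#FFFFFF"       # no annotation: white


def _parse_hex(color: str) -> tuple[int, int, int]:
    if not _HEX.match(color):
        raise ConfigError(f"bad color {color!r} (expected #RRGGBB)")
    return int(color[1:3], 16), int(color[3:5], 16), int(color[5:7], 16)


def _to_hex(rgb: Sequence[float]) -> str:
    return "#%02X%02X%02X" % tuple(int(round(min(255, max(0, c)))) for c in rgb)


@dataclass
class ColorScale:
    """Three-anchor diverging scale, linear per RGB channel between anchors."""

    domain: tuple[float, float, float] = (-2.0, 0.0, 2.0)
    range: tuple[str, str, str] = ("#0000FF", "#FFFFFF", "#FF0000")

    def __post_init__(self) -> None:
        lo, mid, hi = self.domain
        if not (lo <= mid <= hi):
            raise ConfigError("color-scale domain must satisfy min <= mid <= max")
        for c in self.range:
            _parse_hex(c)

    def __call__(self, value: float) -> str:
        lo, mid, hi = self.domain
        c_lo, c_mid, c_hi = (_parse_hex(c) for c in self.range)
        if value <= lo:
            return _to_hex(c_lo)
        if value >= hi:
            return _to_hex(c_hi)
        if value <= mid:
            span = mid - lo
            t = 0.0 if span == 0 else (value - lo) / span
            a, b = c_lo, c_mid
        else:
            span = hi - mid
            t = 0.0 if span == 0 else (value - mid) / span
            a, b = c_mid, c_hi
        return _to_hex([a[i] + (b[i] - a[i]) * t for i in range(3)])


@dataclass
class SizeScale:
    domain: tuple[float, float] = (0.0, 1.0)
    size_range: tuple[float, float] = (16.0, 64.0)

    def __call__(self, value: float) -> float:
        lo, hi = self.domain
        t = 0.5 if hi == lo else (value - lo) / (hi - lo)
        t = min(1.0, max(0.0, t))
        s_lo, s_hi = self.size_range
        return s_lo + (s_hi - s_lo) * t


@dataclass
class Threshold:
    """Visibility predicate: keep a node when ``value <op> cutoff`` holds
    (optionally on ``|value|``)."""

    op: str = ">="
    cutoff: float = 1.0
    absolute: bool = True

    _OPS = {">=": lambda a, b: a >= b, ">": lambda a, b: a > b,
            "<=": lambda a, b: a <= b, "<": lambda a, b: a < b}

    def __call__(self, value: float) -> bool:
        if math.isnan(value):
            return False
        v = abs(value) if self.absolute else value
        try:
            return self._OPS[self.op](v, self.cutoff)
        except KeyError:
            raise ConfigError(f"unknown threshold operator {self.op!r}") from None


@dataclass
class GlyphSpec:
    """A small chart drawn instead of the node shape (time-series rendering)."""

    kind: str  # "bar" | "line"
    group_names: list[str]
    values: list[float]

    def __post_init__(self) -> None:
        if self.kind not in ("bar", "line"):
            raise ConfigError(f"unknown glyph kind {self.kind!r}")
        if len(self.values) != len(self.group_names):
            raise ConfigError("glyph value vector length must equal group count")


TARGETS = ("fill_color", "node_size", "line_width", "visibility",
           "time_series_glyph", "compartment", "reaction_direction")

_SCALE_FOR_TARGET = {
    "fill_color": ColorScale,
    "node_size": SizeScale,
    "line_width": SizeScale,
    "visibility": Threshold,
}


@dataclass
class ProjectionSpec:
    series_name: str
    samples: list[str] = field(default_factory=list)  # names, or one formula
    formula: Optional[str] = None
    target: str = "fill_color"
    scale: object = None
    missing_policy: str = "default_appearance"  # | hide | neutral_color
    neutral_color: str = "#C0C0C0"
    glyph_kind: str = "bar"
    glyph_groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ConfigError(f"unknown projection target {self.target!r}")
        if self.missing_policy not in ("default_appearance", "hide", "neutral_color"):
            raise ConfigError(f"unknown missing policy {self.missing_policy!r}")
        expected = _SCALE_FOR_TARGET.get(self.target)
        if self.scale is None and expected is not None:
            self.scale = expected()
        if expected is not None and not isinstance(self.scale, expected):
            raise ConfigError(
                f"target {self.target!r} needs a {expected.__name__}, "
                f"got {type(self.scale).__name__}"
            )


# -- row -> entity mapping --------------------------------------------------

def map_rows_to_entities(
    series: DataSeries,
    model: NetworkModel,
    mapping: Optional["IdMappingTable"] = None,
) -> dict[int, set[str]]:
    """Map each series row to the entities it identifies.

    A row matches an entity when the row's identifier set (expanded through
    the optional mapping table) intersects the entity's id or xref
    accessions.  Matching is case-sensitive and exact.  Unmapped rows are a
    normal outcome, reported via the log.
    """
    accession_index: dict[str, set[str]] = {}
    for eid, ent in model.entities.items():
        accession_index.setdefault(eid, set()).add(eid)
        for _, acc in ent.xrefs:
            accession_index.setdefault(acc, set()).add(eid)

    result: dict[int, set[str]] = {}
    unmapped = 0
    for i, ids in enumerate(series.row_ids):
        lookup = mapping.translate_set(ids) if mapping else ids
        hits: set[str] = set()
        for acc in lookup:
            hits |= accession_index.get(acc, set())
        if hits:
            result[i] = hits
        else:
            unmapped += 1
    if unmapped:
        logger.info("projection: %d of %d rows unmapped", unmapped, series.n_rows)
    return result


# -- temporary / derived samples --------------------------------------------

def mean_sample(series: DataSeries, selected: Sequence[str]) -> np.ndarray:
    """Per-row mean over the non-missing values of the selected samples.

    A single selected sample is returned unchanged; a row missing in every
    selected sample stays missing.
    """
    if not selected:
        raise ConfigError("no samples selected")
    cols = np.column_stack([series.column(s) for s in selected])
    if cols.shape[1] == 1:
        return cols[:, 0].copy()
    return _nanmean_cols(cols)


def _nanmean_cols(cols: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
        return np.nanmean(cols, axis=1)


# Expression evaluator ------------------------------------------------------
#
# Grammar (row-wise over samples):
#   expr    := term (('+'|'-') term)*
#   term    := factor (('*'|'/') factor)*
#   factor  := unary ('^' factor)?          (right-associative)
#   unary   := '-' unary | atom
#   atom    := NUMBER | NAME '(' args ')' | NAME | '(' expr ')'
#
# Built-ins: mean (missing-skipping, matching mean_sample), log2, log10, abs,
# min, max, zscore (normalizes over the rows of its argument, ddof=0).
# Arithmetic operators propagate missing values; division by zero yields a
# missing value with a warning.  Additional functions can be registered, so an
# external statistics engine can be plugged in per function name.

_TOKEN = re.compile(
    r"\s*(?:(?P<num>\d+(?:\.\d*)?(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_.]*)"
    r"|(?P<op>[-+*/^(),]))"
)

_FUNCTION_REGISTRY: dict[str, Callable[..., np.ndarray]] = {}


def register_function(name: str, fn: Callable[..., np.ndarray]) -> None:
    """Extension hook: make *fn* callable from sample formulas by *name*."""
    _FUNCTION_REGISTRY[name] = fn


def _nan_binary(op: Callable, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = op(a, b)
    return np.where(np.isnan(a) | np.isnan(b), np.nan, out)


class _Parser:
    def __init__(self, text: str, series: DataSeries):
        self.series = series
        self.tokens: list[tuple[str, str]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if m is None:
                if text[pos:].strip():
                    raise ExpressionError(f"unexpected character {text[pos:].strip()[0]!r}")
                break
            pos = m.end()
            for kind in ("num", "name", "op"):
                if m.group(kind) is not None:
                    self.tokens.append((kind, m.group(kind)))
        self.i = 0

    def peek(self) -> Optional[tuple[str, str]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise ExpressionError("unexpected end of expression")
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        tok = self.next()
        if tok[1] != value:
            raise ExpressionError(f"expected {value!r}, found {tok[1]!r}")

    def parse(self) -> np.ndarray:
        result = self.expr()
        if self.peek() is not None:
            raise ExpressionError(f"trailing token {self.peek()[1]!r}")
        return result

    def expr(self) -> np.ndarray:
        left = self.term()
        while self.peek() and self.peek()[1] in "+-":
            op = self.next()[1]
            right = self.term()
            left = _nan_binary(np.add if op == "+" else np.subtract, left, right)
        return left

    def term(self) -> np.ndarray:
        left = self.factor()
        while self.peek() and self.peek()[1] in "*/":
            op = self.next()[1]
            right = self.factor()
            if op == "*":
                left = _nan_binary(np.multiply, left, right)
            else:
                out = _nan_binary(np.divide, left, right)
                zero_div = (right == 0) & ~np.isnan(left) & ~np.isnan(right)
                if np.any(zero_div):
                    logger.warning("division by zero in %d row(s); result missing",
                                   int(np.sum(zero_div)))
                left = np.where(zero_div, np.nan, out)
        return left

    def factor(self) -> np.ndarray:
        base = self.unary()
        if self.peek() and self.peek()[1] == "^":
            self.next()
            exponent = self.factor()
            return _nan_binary(np.power, base, exponent)
        return base

    def unary(self) -> np.ndarray:
        if self.peek() and self.peek()[1] == "-":
            self.next()
            return -self.unary()
        return self.atom()

    def atom(self) -> np.ndarray:
        kind, value = self.next()
        n = self.series.n_rows
        if kind == "num":
            return np.full(n, float(value))
        if kind == "name":
            if self.peek() and self.peek()[1] == "(":
                self.next()
                args = []
                if self.peek() and self.peek()[1] != ")":
                    args.append(self.expr())
                    while self.peek() and self.peek()[1] == ",":
                        self.next()
                        args.append(self.expr())
                self.expect(")")
                return self.call(value, args)
            if value in self.series.samples:
                return self.series.column(value).copy()
            raise ExpressionError(f"unknown sample {value!r}")
        if value == "(":
            inner = self.expr()
            self.expect(")")
            return inner
        raise ExpressionError(f"unexpected token {value!r}")

    def call(self, name: str, args: list[np.ndarray]) -> np.ndarray:
        if name in _FUNCTION_REGISTRY:
            return np.asarray(_FUNCTION_REGISTRY[name](*args), dtype=float)
        if not args:
            raise ExpressionError(f"function {name!r} needs arguments")
        with np.errstate(invalid="ignore", divide="ignore"):
            if name == "mean":
                return _nanmean_cols(np.column_stack(args))
            if name == "min":
                if len(args) == 1:
                    return args[0]
                return np.nanmin(np.column_stack(args), axis=1)
            if name == "max":
                if len(args) == 1:
                    return args[0]
                return np.nanmax(np.column_stack(args), axis=1)
            if name == "abs":
                return np.abs(args[0])
            if name == "log2":
                out = np.log2(args[0])
                return np.where(args[0] <= 0, np.nan, out)
            if name == "log10":
                out = np.log10(args[0])
                return np.where(args[0] <= 0, np.nan, out)
            if name == "zscore":
                x = args[0]
                mu = np.nanmean(x)
                sd = np.nanstd(x)
                if sd == 0 or np.isnan(sd):
                    return np.full_like(x, np.nan)
                return (x - mu) / sd
        raise ExpressionError(f"unknown function {name!r}")


def evaluate_expression(series: DataSeries, expression: str) -> np.ndarray:
    """Evaluate a row-wise formula over sample names; returns one value per row."""
    if not expression.strip():
        raise ExpressionError("empty expression")
    return _Parser(expression, series).parse()


def derive_sample(series: DataSeries, expression: str,
                  name: Optional[str] = None) -> str:
    """Evaluate a formula and append the result as a new named sample."""
    values = evaluate_expression(series, expression)
    name = name or f"derived:{expression.strip()}"
    series.add_sample(name, values)
    return name


# -- projection proper ------------------------------------------------------

def _values_for_spec(series: DataSeries, spec: ProjectionSpec) -> np.ndarray:
    if spec.formula:
        return evaluate_expression(series, spec.formula)
    if not spec.samples:
        raise ConfigError("projection spec selects no samples and no formula")
    return mean_sample(series, spec.samples)


def project(
    model: NetworkModel,
    series: DataSeries,
    spec: ProjectionSpec,
    row_mapping: dict[int, set[str]],
) -> PropertyLayer:
    """Build a projection-scope property layer from a spec.

    Rows mapping to the same entity are averaged before scaling (matching the
    multi-sample mean convention).  Unmapped entities follow the spec's
    missing policy.  The returned layer is also installed on the model.
    """
    if spec.target == "time_series_glyph":
        return project_time_series(model, series, spec.glyph_groups or
                                   list(series.groups), spec.glyph_kind,
                                   row_mapping, spec)
    values = _values_for_spec(series, spec)

    per_entity: dict[str, list[float]] = {}
    for row, entities in row_mapping.items():
        v = float(values[row])
        for eid in entities:
            per_entity.setdefault(eid, []).append(v)

    layer = PropertyLayer(Scope.PROJECTION)
    for eid in sorted(model.entities):
        vals = [v for v in per_entity.get(eid, []) if not math.isnan(v)]
        if not vals:
            _apply_missing(layer, eid, spec)
            continue
        value = float(np.mean(vals))
        _apply_target(layer, model, eid, value, spec)
    _install(model, layer)
    return layer


def _apply_target(layer: PropertyLayer, model: NetworkModel, eid: str,
                  value: float, spec: ProjectionSpec) -> None:
    if spec.target == "fill_color":
        layer.set(eid, "fill_color", spec.scale(value))
    elif spec.target == "node_size":
        s = spec.scale(value)
        layer.set(eid, "size", (s, s))
    elif spec.target == "line_width":
        layer.set(eid, "line_width", spec.scale(value))
    elif spec.target == "visibility":
        layer.set(eid, "visible", bool(spec.scale(value)))
    elif spec.target == "compartment":
        layer.set(eid, "fill_color",
                  compartment_ambiguity_color(model.entities[eid]))
    elif spec.target == "reaction_direction":
        # a signed value flips a *reversible* reaction's rendered direction
        for rid, rxn in model.reactions.items():
            if eid in rxn.participant_ids or eid in rxn.catalysts:
                if rxn.reversible and value < 0:
                    layer.set(rid, "direction", "reverse")


def _apply_missing(layer: PropertyLayer, eid: str, spec: ProjectionSpec) -> None:
    if spec.missing_policy == "hide":
        layer.set(eid, "visible", False)
    elif spec.missing_policy == "neutral_color" and spec.target == "fill_color":
        layer.set(eid, "fill_color", spec.neutral_color)
    # default_appearance: no assignment, lower layers show through


def _install(model: NetworkModel, layer: PropertyLayer) -> None:
    from .model import Dirty  # local to keep the import graph simple
    model.layers[Scope.PROJECTION] = layer
    for cid, props in layer.assignments.items():
        model._touch(cid, Dirty.TOPOLOGICAL if "visible" in props else Dirty.VISUAL)


def project_time_series(
    model: NetworkModel,
    series: DataSeries,
    ordered_groups: Sequence[str],
    glyph_kind: str,
    row_mapping: dict[int, set[str]],
    spec: Optional[ProjectionSpec] = None,
) -> PropertyLayer:
    """Attach per-entity glyphs: one group-mean value per ordered group."""
    if not ordered_groups:
        raise ConfigError("time-series projection needs ordered sample groups")
    for g in ordered_groups:
        if g not in series.groups or not series.groups[g]:
            raise ConfigError(f"empty or unknown sample group {g!r}")
    group_means = np.column_stack(
        [mean_sample(series, series.groups[g]) for g in ordered_groups]
    )
    layer = PropertyLayer(Scope.PROJECTION)
    per_entity: dict[str, list[np.ndarray]] = {}
    for row, entities in row_mapping.items():
        for eid in entities:
            per_entity.setdefault(eid, []).append(group_means[row])
    for eid in sorted(per_entity):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vec = np.nanmean(np.vstack(per_entity[eid]), axis=0)
        if np.all(np.isnan(vec)):
            continue
        layer.set(eid, "shape", GlyphSpec(
            kind=glyph_kind, group_names=list(ordered_groups),
            values=[float(v) for v in vec],
        ))
    _install(model, layer)
    return layer


def compartment_ambiguity_color(entity) -> str:
    """Certainty of subcellular-location annotation as a color.

    One compartment: unambiguous (red); several: ambiguous (rose); none: no
    information (white).
    """
    n = len(set(entity.compartments))
    if n == 1:
        return UNAMBIGUOUS_COLOR
    if n >= 2:
        return AMBIGUOUS_COLOR
    return NO_INFO_COLOR
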