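"""Bounded temporal logic over multiscale traces: parsing and evaluation.

A probabilistic query has the form ``P <cmp> theta [ <formula> ]``; the
enclosed formula combines Boolean connectives, the bounded temporal
operators ``G[a,b]``, ``F[a,b]`` and ``U[a,b]``, and comparisons of
numeric expressions.  Numeric expressions reference numeric state
variables (``{name}(scaleAndSubsystem = scale.subsystem)``), apply
arithmetic functions, statistical functions over collections of spatial
measure values or time-windowed samples, and the forward difference
``d(...)``.

Semantics are sample-based: temporal operators quantify over the
*observed* timepoints in their window, with no interpolation; the first
timestamp of the trace is the temporal origin.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import (BindingError, EvaluationError, HorizonError,
                     NumericError, ParseError, RangeError)
from .magraph import MAGraph, ScaleSubsystem
from .registry import SpatialRegistry, default_registry
from .traces import Trace

logger = logging.getLogger(__name__)

UNARY_STAT_FUNCTIONS = frozenset({
    "count", "sum", "avg", "mean", "min", "max", "median", "mode", "product",
    "stdev", "var", "skew", "kurtosis", "geomean", "harmean"})
BINARY_STAT_FUNCTIONS = frozenset({"covariance"})
QUANTILE_STAT_FUNCTIONS = frozenset({"percentile", "quartile"})
UNARY_ARITH_FUNCTIONS = frozenset({
    "abs", "ceil", "floor", "round", "sign", "sqrt", "trunc"})
BINARY_ARITH_FUNCTIONS = frozenset({
    "add", "div", "log", "mod", "multiply", "power", "subtract"})
SET_FUNCTIONS = {"union": "union", "intersection": "intersection",
                 "difference": "difference"}

_EQ_RTOL = 1e-9


def _approx_equal(a: float, b: float) -> bool:
    return abs(a - b) <= _EQ_RTOL * max(1.0, abs(a), abs(b))


_COMPARATORS = {
    "<": lambda a, b: a < b and not _approx_equal(a, b),
    "<=": lambda a, b: a < b or _approx_equal(a, b),
    "=": _approx_equal,
    ">=": lambda a, b: a > b or _approx_equal(a, b),
    ">": lambda a, b: a > b and not _approx_equal(a, b),
}


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Query:
    comparator: str            # one of <, <=, >=, >
    threshold: float           # strictly inside (0, 1)
    body: "Formula"
    text: str = ""

    def compare(self, probability: float) -> bool:
        return _COMPARATORS[self.comparator](probability, self.threshold)

    def to_text(self) -> str:
        return f"P {self.comparator} {_num(self.threshold)} [{self.body.to_text()}]"


class Formula:
    def to_text(self) -> str:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class Comparison(Formula):
    left: "NumericExpression"
    op: str
    right: "NumericExpression"

    def to_text(self):
        return f"({self.left.to_text()} {self.op} {self.right.to_text()})"


@dataclass(frozen=True)
class Not(Formula):
    operand: Formula

    def to_text(self):
        return f"(not {self.operand.to_text()})"


@dataclass(frozen=True)
class BoolOp(Formula):
    op: str  # 'and' | 'or' | '=>'
    left: Formula
    right: Formula

    def to_text(self):
        return f"({self.left.to_text()} {self.op} {self.right.to_text()})"


@dataclass(frozen=True)
class TemporalUnary(Formula):
    op: str  # 'G' | 'F'
    low: float
    high: float
    operand: Formula

    def to_text(self):
        return (f"{self.op} [{_num(self.low)}, {_num(self.high)}] "
                f"{self.operand.to_text()}")


@dataclass(frozen=True)
class Until(Formula):
    low: float
    high: float
    left: Formula
    right: Formula

    def to_text(self):
        return (f"({self.left.to_text()} U [{_num(self.low)}, "
                f"{_num(self.high)}] {self.right.to_text()})")


class NumericExpression:
    def to_text(self) -> str:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class Literal(NumericExpression):
    value: float

    def to_text(self):
        return _num(self.value)


@dataclass(frozen=True)
class VariableRef(NumericExpression):
    name: str
    scale_subsystem: ScaleSubsystem

    def to_text(self):
        return f"{{{self.name}}}(scaleAndSubsystem = {self.scale_subsystem})"


@dataclass(frozen=True)
class Difference(NumericExpression):
    operand: NumericExpression

    def to_text(self):
        return f"d({self.operand.to_text()})"


@dataclass(frozen=True)
class ArithFunction(NumericExpression):
    name: str
    operands: tuple[NumericExpression, ...]

    def to_text(self):
        args = ", ".join(op.to_text() for op in self.operands)
        return f"{self.name}({args})"


@dataclass(frozen=True)
class StatFunction(NumericExpression):
    name: str
    collections: tuple["Collection", ...]
    quantile: float | None = None

    def to_text(self):
        args = ", ".join(c.to_text() for c in self.collections)
        if self.quantile is not None:
            args += f", {_num(self.quantile)}"
        return f"{self.name}({args})"


class Collection:
    pass


@dataclass(frozen=True)
class MeasureCollection(Collection):
    measure: str
    entities: "EntitySetExpression"

    def to_text(self):
        return f"{self.measure}({self.entities.to_text()})"


@dataclass(frozen=True)
class TemporalCollection(Collection):
    low: float
    high: float
    expression: NumericExpression

    def to_text(self):
        return (f"[{_num(self.low)}, {_num(self.high)}] "
                f"{self.expression.to_text()}")


class EntitySetExpression:
    pass


@dataclass(frozen=True)
class MeasureConstraint:
    measure: str
    op: str
    value: float

    def to_text(self):
        return f"{self.measure} {self.op} {_num(self.value)}"


@dataclass(frozen=True)
class ScaleSubsystemConstraint:
    op: str  # '=', '<', '<='
    reference: ScaleSubsystem

    def to_text(self):
        return f"scaleAndSubsystem {self.op} {self.reference}"


@dataclass(frozen=True)
class EntityFilter(EntitySetExpression):
    entity_type: str
    constraints: tuple = ()

    def to_text(self):
        if not self.constraints:
            return f"filter({self.entity_type})"
        body = " and ".join(c.to_text() for c in self.constraints)
        return f"filter({self.entity_type}, {body})"


@dataclass(frozen=True)
class EntitySetOp(EntitySetExpression):
    op: str  # union | intersection | difference
    left: EntitySetExpression
    right: EntitySetExpression

    def to_text(self):
        return f"{self.op}({self.left.to_text()}, {self.right.to_text()})"


def _num(value: float) -> str:
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"""
    (?P<number>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op><=|>=|=>|[<>=^\\{}()\[\],.\-])
  | (?P<uni>[∧∨¬⇒≤∩∪])
  | (?P<ws>\s+)
  | (?P<bad>.)
""", re.VERBOSE)

_UNICODE_MAP = {"∧": "and", "∨": "or", "¬": "not", "⇒": "=>", "≤": "<=",
                "∩": "∩", "∪": "∪"}


@dataclass(frozen=True)
class _Token:
    kind: str   # 'number' | 'ident' | 'op'
    text: str
    line: int
    column: int


def _tokenize(text: str) -> list[_Token]:
    tokens = []
    line, line_start = 1, 0
    for match in _TOKEN_RE.finditer(text):
        kind = match.lastgroup
        value = match.group()
        if kind == "ws":
            newlines = value.count("\n")
            if newlines:
                line += newlines
                line_start = match.end() - (len(value) - value.rfind("\n") - 1)
            continue
        column = match.start() - line_start + 1
        if kind == "bad":
            raise ParseError(f"unexpected character {value!r}", line, column)
        if kind == "uni":
            mapped = _UNICODE_MAP[value]
            kind = "ident" if mapped.isalpha() else "op"
            value = mapped
        tokens.append(_Token(kind, value, line, column))
    return tokens


# ---------------------------------------------------------------------------
# Parser (recursive descent)
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, tokens, graph: MAGraph, registry: SpatialRegistry):
        self.tokens = tokens
        self.pos = 0
        self.graph = graph
        self.registry = registry

    # -- token plumbing ------------------------------------------------

    def peek(self, offset=0) -> _Token | None:
        index = self.pos + offset
        return self.tokens[index] if index < len(self.tokens) else None

    def next(self) -> _Token:
        token = self.peek()
        if token is None:
            raise ParseError("unexpected end of input")
        self.pos += 1
        return token

    def expect(self, text: str) -> _Token:
        token = self.peek()
        if token is None or token.text != text:
            found = token.text if token else "end of input"
            raise ParseError(f"expected {text!r}, found {found!r}",
                             token.line if token else None,
                             token.column if token else None)
        return self.next()

    def at(self, text: str) -> bool:
        token = self.peek()
        return token is not None and token.text == text

    def error(self, message: str):
        token = self.peek()
        raise ParseError(message, token.line if token else None,
                         token.column if token else None)

    # -- grammar -------------------------------------------------------

    def parse_query(self) -> Query:
        self.expect("P")
        comparator = self._comparator(allow_equal=False)
        theta = self._number()
        if not (0.0 < theta < 1.0):
            raise RangeError(f"probability threshold {theta} not in (0, 1)")
        self.expect("[")
        body = self.formula()
        self.expect("]")
        if self.peek() is not None:
            self.error("trailing input after query")
        return Query(comparator, theta, body)

    def formula(self) -> Formula:
        left = self.or_formula()
        if self.at("=>"):
            self.next()
            return BoolOp("=>", left, self.formula())
        return left

    def or_formula(self) -> Formula:
        left = self.and_formula()
        while self._at_ident("or") or self._at_ident("V"):
            self.next()
            left = BoolOp("or", left, self.and_formula())
        return left

    def and_formula(self) -> Formula:
        left = self.until_formula()
        while self._at_ident("and") or self.at("^"):
            self.next()
            left = BoolOp("and", left, self.until_formula())
        return left

    def until_formula(self) -> Formula:
        left = self.unary_formula()
        if self._at_ident("U"):
            self.next()
            low, high = self._time_bounds()
            return Until(low, high, left, self.unary_formula())
        return left

    def unary_formula(self) -> Formula:
        token = self.peek()
        if token is None:
            raise ParseError("unexpected end of formula")
        if token.text == "not" or token.text == "!":
            self.next()
            return Not(self.unary_formula())
        if token.kind == "ident" and token.text in ("G", "F"):
            self.next()
            low, high = self._time_bounds()
            return TemporalUnary(token.text, low, high, self.unary_formula())
        if token.text == "(":
            self.next()
            inner = self.formula()
            self.expect(")")
            if self.peek() is not None and self.peek().text in _COMPARATORS \
                    and isinstance(inner, Comparison) is False:
                self.error("parenthesized numeric expressions are not "
                           "supported; use functional arithmetic")
            return inner
        return self.comparison()

    def comparison(self) -> Comparison:
        left = self.numeric()
        op = self._comparator(allow_equal=True)
        right = self.numeric()
        return Comparison(left, op, right)

    def numeric(self) -> NumericExpression:
        token = self.peek()
        if token is None:
            raise ParseError("unexpected end of numeric expression")
        if token.kind == "number":
            return Literal(self._number())
        if token.text == "-":
            self.next()
            return Literal(-self._number())
        if token.text == "{":
            return self._variable_ref()
        if token.kind == "ident":
            name = token.text
            if name == "d":
                self.next()
                self.expect("(")
                inner = self.numeric()
                self.expect(")")
                return Difference(inner)
            if name in UNARY_ARITH_FUNCTIONS:
                self.next()
                self.expect("(")
                inner = self.numeric()
                self.expect(")")
                return ArithFunction(name, (inner,))
            if name in BINARY_ARITH_FUNCTIONS:
                self.next()
                self.expect("(")
                first = self.numeric()
                self.expect(",")
                second = self.numeric()
                self.expect(")")
                return ArithFunction(name, (first, second))
            if name in UNARY_STAT_FUNCTIONS:
                self.next()
                self.expect("(")
                collection = self.collection()
                self.expect(")")
                return StatFunction(name, (collection,))
            if name in BINARY_STAT_FUNCTIONS:
                self.next()
                self.expect("(")
                first = self.collection()
                self.expect(",")
                second = self.collection()
                self.expect(")")
                return StatFunction(name, (first, second))
            if name in QUANTILE_STAT_FUNCTIONS:
                self.next()
                self.expect("(")
                collection = self.collection()
                self.expect(",")
                q = self._number()
                self.expect(")")
                limit = 100.0 if name == "percentile" else 4.0
                if not (0.0 <= q <= limit):
                    raise RangeError(f"{name} argument {q} out of range")
                return StatFunction(name, (collection,), q)
        self.error(f"cannot parse numeric expression at {token.text!r}")

    def collection(self) -> Collection:
        token = self.peek()
        if token is not None and token.text == "[":
            low, high = self._time_bounds()
            return TemporalCollection(low, high, self.numeric())
        if token is not None and token.kind == "ident" \
                and token.text in self.registry.measures:
            self.next()
            self.expect("(")
            entities = self.entity_set()
            self.expect(")")
            return MeasureCollection(token.text, entities)
        self.error("expected a spatial-measure collection or '[a, b]' window")

    def entity_set(self) -> EntitySetExpression:
        left = self._entity_primary()
        while True:
            token = self.peek()
            if token is None:
                break
            if token.text == "∪":
                self.next()
                left = EntitySetOp("union", left, self._entity_primary())
            elif token.text == "∩":
                self.next()
                left = EntitySetOp("intersection", left, self._entity_primary())
            elif token.text == "\\":
                self.next()
                left = EntitySetOp("difference", left, self._entity_primary())
            else:
                break
        return left

    def _entity_primary(self) -> EntitySetExpression:
        token = self.peek()
        if token is None:
            raise ParseError("unexpected end of entity-set expression")
        if token.text == "(":
            self.next()
            inner = self.entity_set()
            self.expect(")")
            return inner
        if token.kind == "ident" and token.text in SET_FUNCTIONS:
            self.next()
            self.expect("(")
            left = self.entity_set()
            self.expect(",")
            right = self.entity_set()
            self.expect(")")
            return EntitySetOp(SET_FUNCTIONS[token.text], left, right)
        if token.kind == "ident" and token.text == "filter":
            self.next()
            self.expect("(")
            type_token = self.next()
            if type_token.text not in self.registry.entity_types:
                raise BindingError(f"unknown entity type {type_token.text!r}")
            constraints = []
            while self.at(","):
                self.next()
                constraints.append(self._constraint())
                while self._at_ident("and") or self.at("^"):
                    self.next()
                    constraints.append(self._constraint())
            self.expect(")")
            return EntityFilter(type_token.text, tuple(constraints))
        if token.kind == "ident" and token.text in self.registry.entity_types:
            self.next()
            return EntityFilter(token.text)
        self.error(f"cannot parse entity-set expression at {token.text!r}")

    def _constraint(self):
        token = self.next()
        if token.text == "scaleAndSubsystem":
            op = self._comparator(allow_equal=True)
            if op not in ("=", "<", "<="):
                raise ParseError(
                    f"scaleAndSubsystem constraints allow =, < and <= only "
                    f"(got {op!r})", token.line, token.column)
            return ScaleSubsystemConstraint(op, self._scale_subsystem())
        if token.kind == "ident" and token.text in self.registry.measures:
            op = self._comparator(allow_equal=True)
            negative = False
            if self.at("-"):
                self.next()
                negative = True
            value = self._number()
            return MeasureConstraint(token.text, op, -value if negative else value)
        raise ParseError(f"unknown constraint subject {token.text!r}",
                         token.line, token.column)

    def _variable_ref(self) -> VariableRef:
        self.expect("{")
        name = self.next()
        if name.kind != "ident":
            raise ParseError(f"expected variable name, found {name.text!r}",
                             name.line, name.column)
        self.expect("}")
        self.expect("(")
        self.expect("scaleAndSubsystem")
        self.expect("=")
        ss = self._scale_subsystem()
        self.expect(")")
        return VariableRef(name.text, ss)

    def _scale_subsystem(self) -> ScaleSubsystem:
        scale = self.next()
        self.expect(".")
        subsystem = self.next()
        if scale.kind != "ident" or subsystem.kind != "ident":
            raise ParseError("expected scale.subsystem",
                             scale.line, scale.column)
        ss = ScaleSubsystem(scale.text, subsystem.text)
        if ss not in self.graph:
            raise BindingError(
                f"scale.subsystem {ss} is not a vertex of the architecture graph")
        return ss

    def _time_bounds(self) -> tuple[float, float]:
        self.expect("[")
        low = self._number()
        self.expect(",")
        high = self._number()
        self.expect("]")
        if low < 0 or high < low:
            raise RangeError(f"invalid time bounds [{low}, {high}]")
        return low, high

    def _comparator(self, allow_equal: bool) -> str:
        token = self.next()
        ops = ("<", "<=", "=", ">=", ">") if allow_equal else ("<", "<=", ">=", ">")
        if token.text not in ops:
            raise ParseError(f"expected comparator, found {token.text!r}",
                             token.line, token.column)
        return token.text

    def _number(self) -> float:
        token = self.next()
        if token.kind != "number":
            raise ParseError(f"expected number, found {token.text!r}",
                             token.line, token.column)
        return float(token.text)

    def _at_ident(self, text: str) -> bool:
        token = self.peek()
        return token is not None and token.kind == "ident" and token.text == text


def parse_query(text: str, graph: MAGraph,
                registry: SpatialRegistry | None = None) -> Query:
    """Parse one probabilistic statement, binding symbols against the graph
    and the active registry."""
    registry = registry if registry is not None else default_registry()
    parser = _Parser(_tokenize(text), graph, registry)
    query = parser.parse_query()
    return Query(query.comparator, query.threshold, query.body, text.strip())


def parse_formula(text: str, graph: MAGraph,
                  registry: SpatialRegistry | None = None) -> Formula:
    """Parse a bare (non-probabilistic) formula; mainly for tests."""
    registry = registry if registry is not None else default_registry()
    parser = _Parser(_tokenize(text), graph, registry)
    formula = parser.formula()
    if parser.peek() is not None:
        parser.error("trailing input after formula")
    return formula


def split_statements(text: str) -> list[str]:
    """Split specification text into statements (';' separators, '#' comments)."""
    stripped = "\n".join(line.split("#", 1)[0] for line in text.splitlines())
    return [chunk.strip() for chunk in stripped.split(";") if chunk.strip()]


def parse_specification(text: str, graph: MAGraph,
                        registry: SpatialRegistry | None = None
                        ) -> list[Query]:
    """Parse a specification file: ';'-separated statements, '#' comments."""
    return [parse_query(chunk, graph, registry)
            for chunk in split_statements(text)]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

class _EmptyCollection(Exception):
    """Internal signal: a statistical function met an empty/undefined input."""

    def __init__(self, message):
        super().__init__(message)
        self.message = message


@dataclass
class Evaluator:
    """Evaluates formulas against one trace under one architecture graph."""

    trace: Trace
    graph: MAGraph
    carry_forward: bool = False
    warnings: list[str] = field(default_factory=list)

    def evaluate(self, formula: Formula) -> bool:
        """Truth value of ``formula`` at the first timepoint of the trace."""
        if len(self.trace) == 0:
            raise EvaluationError("cannot evaluate over an empty trace")
        needed = required_horizon(formula)
        if needed > self.trace.duration + 1e-9:
            raise HorizonError(
                f"formula requires a horizon of {needed} time units but the "
                f"trace spans only {self.trace.duration} "
                f"(deficit {needed - self.trace.duration})")
        return self.formula_at(formula, 0)

    # -- formulas ------------------------------------------------------

    def formula_at(self, f: Formula, index: int) -> bool:
        if isinstance(f, Comparison):
            try:
                left = self.numeric_at(f.left, index)
                right = self.numeric_at(f.right, index)
            except _EmptyCollection as signal:
                self._warn(f"comparison falsified: {signal.message}")
                return False
            return _COMPARATORS[f.op](left, right)
        if isinstance(f, Not):
            return not self.formula_at(f.operand, index)
        if isinstance(f, BoolOp):
            if f.op == "and":
                return self.formula_at(f.left, index) and \
                    self.formula_at(f.right, index)
            if f.op == "or":
                return self.formula_at(f.left, index) or \
                    self.formula_at(f.right, index)
            return (not self.formula_at(f.left, index)) or \
                self.formula_at(f.right, index)
        if isinstance(f, TemporalUnary):
            window = self._window(index, f.low, f.high)
            if f.op == "G":
                return all(self.formula_at(f.operand, j) for j in window)
            return any(self.formula_at(f.operand, j) for j in window)
        if isinstance(f, Until):
            # Left operand must hold at the current instant and at every
            # observed timepoint strictly before the witness of the right
            # operand.
            times = self.trace.times
            for j in self._window(index, f.low, f.high):
                if self.formula_at(f.right, j):
                    if all(self.formula_at(f.left, k)
                           for k in range(index, len(times))
                           if k == index or times[k] < times[j]):
                        return True
            return False
        raise TypeError(f"unknown formula node {type(f).__name__}")

    def _window(self, index: int, low: float, high: float) -> list[int]:
        t = self.trace.times[index]
        eps = 1e-9 * max(1.0, abs(t) + high)
        return [j for j, tj in enumerate(self.trace.times)
                if t + low - eps <= tj <= t + high + eps]

    # -- numeric expressions ------------------------------------------

    def numeric_at(self, e: NumericExpression, index: int) -> float:
        if isinstance(e, Literal):
            return e.value
        if isinstance(e, VariableRef):
            return self._lookup(e, index)
        if isinstance(e, Difference):
            if index + 1 >= len(self.trace):
                raise HorizonError(
                    "d() requires a successor timepoint beyond the trace end")
            return (self.numeric_at(e.operand, index + 1)
                    - self.numeric_at(e.operand, index))
        if isinstance(e, ArithFunction):
            args = [self.numeric_at(op, index) for op in e.operands]
            return _apply_arith(e.name, args)
        if isinstance(e, StatFunction):
            values = [self._materialize(c, index) for c in e.collections]
            return _apply_stat(e.name, values, e.quantile)
        raise TypeError(f"unknown numeric node {type(e).__name__}")

    def _lookup(self, ref: VariableRef, index: int) -> float:
        start = index if not self.carry_forward else None
        indices = [index] if not self.carry_forward else range(index, -1, -1)
        for j in indices:
            value = self.trace.timepoints[j].lookup(ref.name, ref.scale_subsystem)
            if value is not None:
                return value
        raise EvaluationError(
            f"variable {ref.name} at {ref.scale_subsystem} missing at "
            f"timepoint index {index}")

    def _materialize(self, collection: Collection, index: int) -> list[float]:
        if isinstance(collection, MeasureCollection):
            entities = self.resolve_entity_set(collection.entities, index)
            return [entity.measure(collection.measure) for entity in entities]
        window = self._window(index, collection.low, collection.high)
        return [self.numeric_at(collection.expression, j) for j in window]

    # -- entity sets ---------------------------------------------------

    def resolve_entity_set(self, expr: EntitySetExpression, index: int):
        timepoint = self.trace.timepoints[index]
        if isinstance(expr, EntityFilter):
            kept = []
            for entity in timepoint.entities:
                if entity.entity_type != expr.entity_type:
                    continue
                if all(self._satisfies(entity, c) for c in expr.constraints):
                    kept.append(entity)
            return kept
        if isinstance(expr, EntitySetOp):
            left = self.resolve_entity_set(expr.left, index)
            right = self.resolve_entity_set(expr.right, index)
            right_ids = {id(e) for e in right}
            if expr.op == "union":
                return left + [e for e in right if id(e) not in
                               {id(x) for x in left}]
            if expr.op == "intersection":
                return [e for e in left if id(e) in right_ids]
            return [e for e in left if id(e) not in right_ids]
        raise TypeError(f"unknown entity-set node {type(expr).__name__}")

    def _satisfies(self, entity, constraint) -> bool:
        if isinstance(constraint, MeasureConstraint):
            return _COMPARATORS[constraint.op](
                entity.measure(constraint.measure), constraint.value)
        if constraint.op == "=":
            return entity.scale_subsystem == constraint.reference
        if constraint.op == "<":
            return self.graph.precedes(entity.scale_subsystem,
                                       constraint.reference)
        return self.graph.precedes_or_equal(entity.scale_subsystem,
                                            constraint.reference)

    def _warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)


def evaluate(formula: Formula, trace: Trace, graph: MAGraph,
             carry_forward: bool = False) -> bool:
    return Evaluator(trace, graph, carry_forward).evaluate(formula)


def required_horizon(node) -> float:
    """Least trace duration guaranteeing full evaluation of ``node``.

    The extra sample step needed by ``d()`` has no fixed duration and is
    enforced at evaluation time instead.
    """
    if isinstance(node, Comparison):
        return max(required_horizon(node.left), required_horizon(node.right))
    if isinstance(node, Not):
        return required_horizon(node.operand)
    if isinstance(node, BoolOp):
        return max(required_horizon(node.left), required_horizon(node.right))
    if isinstance(node, TemporalUnary):
        return node.high + required_horizon(node.operand)
    if isinstance(node, Until):
        return node.high + max(required_horizon(node.left),
                               required_horizon(node.right))
    if isinstance(node, (Literal, VariableRef)):
        return 0.0
    if isinstance(node, Difference):
        return required_horizon(node.operand)
    if isinstance(node, ArithFunction):
        return max(required_horizon(op) for op in node.operands)
    if isinstance(node, StatFunction):
        return max(required_horizon(c) for c in node.collections)
    if isinstance(node, MeasureCollection):
        return 0.0
    if isinstance(node, TemporalCollection):
        return node.high + required_horizon(node.expression)
    raise TypeError(f"unknown node {type(node).__name__}")


# ---------------------------------------------------------------------------
# Arithmetic / statistical function application
# ---------------------------------------------------------------------------

def _apply_arith(name: str, args: list[float]) -> float:
    x = args[0]
    if name == "abs":
        return abs(x)
    if name == "ceil":
        return float(math.ceil(x))
    if name == "floor":
        return float(math.floor(x))
    if name == "round":
        return float(round(x))
    if name == "sign":
        return float((x > 0) - (x < 0))
    if name == "sqrt":
        if x < 0:
            raise NumericError(f"sqrt of negative value {x}")
        return math.sqrt(x)
    if name == "trunc":
        return float(math.trunc(x))
    y = args[1]
    if name == "add":
        return x + y
    if name == "subtract":
        return x - y
    if name == "multiply":
        return x * y
    if name == "div":
        if y == 0:
            raise NumericError("division by zero")
        return x / y
    if name == "mod":
        if y == 0:
            raise NumericError("modulo by zero")
        return math.fmod(x, y)
    if name == "power":
        try:
            return float(math.pow(x, y))
        except (ValueError, OverflowError) as exc:
            raise NumericError(f"power({x}, {y}) undefined") from exc
    if name == "log":
        if x <= 0 or y <= 0 or y == 1:
            raise NumericError(f"log({x}, base {y}) undefined")
        return math.log(x) / math.log(y)
    raise NumericError(f"unknown arithmetic function {name!r}")


def _apply_stat(name: str, collections: list[list[float]],
                quantile: float | None) -> float:
    values = np.asarray(collections[0], dtype=float)
    if name == "count":
        return float(len(values))
    if len(values) == 0:
        raise _EmptyCollection(f"{name} over an empty collection")
    if name in ("avg", "mean"):
        return float(values.mean())
    if name == "sum":
        return float(values.sum())
    if name == "min":
        return float(values.min())
    if name == "max":
        return float(values.max())
    if name == "median":
        return float(np.median(values))
    if name == "product":
        return float(values.prod())
    if name == "mode":
        uniques, counts = np.unique(values, return_counts=True)
        return float(uniques[counts == counts.max()].min())
    if name == "stdev":
        if len(values) < 2:
            raise _EmptyCollection("stdev needs at least two values")
        return float(values.std(ddof=1))
    if name == "var":
        if len(values) < 2:
            raise _EmptyCollection("var needs at least two values")
        return float(values.var(ddof=1))
    if name == "skew":
        result = float(sps.skew(values, bias=True))
        if not math.isfinite(result):
            raise _EmptyCollection("skew undefined for this collection")
        return result
    if name == "kurtosis":
        result = float(sps.kurtosis(values, fisher=True, bias=True))
        if not math.isfinite(result):
            raise _EmptyCollection("kurtosis undefined for this collection")
        return result
    if name == "geomean":
        if np.any(values < 0):
            raise NumericError("geomean of negative values")
        return float(sps.gmean(values))
    if name == "harmean":
        if np.any(values <= 0):
            raise NumericError("harmean of non-positive values")
        return float(sps.hmean(values))
    if name == "covariance":
        other = np.asarray(collections[1], dtype=float)
        if len(other) != len(values):
            raise NumericError(
                f"covariance needs equal-length collections "
                f"({len(values)} vs {len(other)})")
        if len(values) < 2:
            raise _EmptyCollection("covariance needs at least two values")
        return float(np.cov(values, other, ddof=1)[0, 1])
    if name == "percentile":
        return float(np.percentile(values, quantile, method="linear"))
    if name == "quartile":
        if quantile not in (1.0, 2.0, 3.0):
            raise NumericError(f"quartile index {quantile} not in {{1, 2, 3}}")
        return float(np.percentile(values, 25.0 * quantile, method="linear"))
    raise NumericError(f"unknown statistical function {name!r}")
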