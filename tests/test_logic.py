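import math
import random
import statistics

import pytest

from mstmc import fixtures
from mstmc.errors import (BindingError, EvaluationError, HorizonError,
                          NumericError, ParseError, RangeError)
from mstmc.logic import (BoolOp, Comparison, Evaluator, Not, TemporalUnary,
                         Until, _apply_stat, evaluate, parse_formula,
                         parse_query, parse_specification, required_horizon)
from mstmc.magraph import MAGraph, ScaleSubsystem

SS = ScaleSubsystem("Scale", "Sub")
GRAPH = MAGraph(SS)


def var(name="x"):
    return f"{{{name}}}(scaleAndSubsystem = Scale.Sub)"


def trace_of(values, times=None):
    return fixtures.numeric_trace("x", values, SS, times)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class TestParseQuery:
    def test_reference_statement(self, organism_graph):
        from mstmc.magraph import ScaleSubsystem as V
        graph = MAGraph(V("Organism", "Human"))
        graph.add_edge(graph.root, V("Intracellular", "RasERKPathway"))
        graph.add_edge(graph.root, V("Cellular", "Cancerous"))
        text = ("P > 0.99 [G[0, 95] (({EGFR}(scaleAndSubsystem = "
                "Intracellular.RasERKPathway) > 20) => (d(count(density("
                "filter(regions, scaleAndSubsystem = Cellular.Cancerous)))) "
                "> 0))]")
        query = parse_query(text, graph)
        assert query.comparator == ">"
        assert query.threshold == 0.99
        assert isinstance(query.body, TemporalUnary)
        assert query.body.op == "G"
        assert query.body.high == 95
        assert isinstance(query.body.operand, BoolOp)
        assert query.body.operand.op == "=>"

    def test_trivial_query(self):
        query = parse_query("P > 0.5 [G[0,0] (1 = 1)]", GRAPH)
        assert query.threshold == 0.5

    def test_threshold_must_be_inside_unit_interval(self):
        with pytest.raises(RangeError):
            parse_query("P > 1 [G[0,0] (1 = 1)]", GRAPH)
        with pytest.raises(RangeError):
            parse_query("P < 0 [G[0,0] (1 = 1)]", GRAPH)

    def test_unknown_vertex_is_binding_error(self):
        with pytest.raises(BindingError):
            parse_query("P > 0.5 [{x}(scaleAndSubsystem = No.Such) > 0]",
                        GRAPH)

    def test_unknown_entity_type_is_binding_error(self):
        with pytest.raises(BindingError):
            parse_query("P > 0.5 [count(area(filter(blobs))) > 0]", GRAPH)

    def test_syntax_error_carries_position(self):
        with pytest.raises(ParseError):
            parse_query("P > 0.5 [G[0,5] (1 +)]", GRAPH)

    def test_unicode_aliases(self):
        a = parse_formula(f"(1 = 1) ∧ ¬(2 = 3)", GRAPH)
        b = parse_formula(f"(1 = 1) and (not (2 = 3))", GRAPH)
        assert a == b

    def test_specification_file_splitting(self):
        text = ("# comment line\n"
                "P > 0.5 [G[0,0] (1 = 1)];\n"
                "P < 0.5 [F[0,0] (1 = 2)]  # trailing comment\n")
        queries = parse_specification(text, GRAPH)
        assert len(queries) == 2
        assert queries[0].comparator == ">"
        assert queries[1].comparator == "<"


class TestParserRoundTrip:
    def test_pretty_print_reparses_identically(self):
        rng = random.Random(2024)
        for _ in range(300):
            formula = _random_formula(rng, depth=3)
            text = formula.to_text()
            assert parse_formula(text, GRAPH) == formula, text


def _random_formula(rng, depth):
    if depth == 0:
        left = _random_numeric(rng, 1)
        op = rng.choice(["<", "<=", "=", ">=", ">"])
        return Comparison(left, op, _random_numeric(rng, 1))
    choice = rng.randrange(6)
    if choice == 0:
        return Not(_random_formula(rng, depth - 1))
    if choice in (1, 2):
        return BoolOp(rng.choice(["and", "or", "=>"]),
                      _random_formula(rng, depth - 1),
                      _random_formula(rng, depth - 1))
    if choice in (3, 4):
        a = rng.randrange(0, 5)
        return TemporalUnary(rng.choice(["G", "F"]), float(a),
                             float(a + rng.randrange(0, 5)),
                             _random_formula(rng, depth - 1))
    a = rng.randrange(0, 4)
    return Until(float(a), float(a + rng.randrange(0, 4)),
                 _random_formula(rng, depth - 1),
                 _random_formula(rng, depth - 1))


def _random_numeric(rng, depth):
    from mstmc.logic import (ArithFunction, Difference, Literal,
                             StatFunction, TemporalCollection, VariableRef)
    if depth == 0 or rng.random() < 0.4:
        if rng.random() < 0.5:
            return Literal(float(rng.randrange(-10, 11)))
        return VariableRef("x", SS)
    choice = rng.randrange(4)
    if choice == 0:
        return Difference(_random_numeric(rng, depth - 1))
    if choice == 1:
        return ArithFunction(rng.choice(["abs", "sqrt", "floor"]),
                             (_random_numeric(rng, depth - 1),))
    if choice == 2:
        return ArithFunction(rng.choice(["add", "multiply", "subtract"]),
                             (_random_numeric(rng, depth - 1),
                              _random_numeric(rng, depth - 1)))
    a = rng.randrange(0, 3)
    collection = TemporalCollection(float(a), float(a + rng.randrange(0, 3)),
                                    _random_numeric(rng, depth - 1))
    return StatFunction(rng.choice(["avg", "min", "max", "count", "sum"]),
                        (collection,))


# ---------------------------------------------------------------------------
# Evaluation semantics
# ---------------------------------------------------------------------------

class TestEvaluate:
    def test_globally_true(self):
        trace = fixtures.constant_trace("x", 1.0, SS, range(11))
        assert evaluate(parse_formula(f"G[0,10] ({var()} > 0)", GRAPH),
                        trace, GRAPH)

    def test_finally_false(self):
        trace = fixtures.constant_trace("x", 1.0, SS, range(11))
        assert not evaluate(parse_formula(f"F[0,10] ({var()} < 0)", GRAPH),
                            trace, GRAPH)

    def test_until_hand_oracle(self):
        trace = trace_of([0, 0, 1])
        holds = parse_formula(f"({var()} = 0) U[0,2] ({var()} = 1)", GRAPH)
        fails = parse_formula(f"({var()} = 1) U[0,2] ({var()} = 0)", GRAPH)
        assert evaluate(holds, trace, GRAPH)
        assert not evaluate(fails, trace, GRAPH)

    def test_difference_is_forward(self):
        trace = trace_of([3, 5, 9])
        evaluator = Evaluator(trace, GRAPH)
        expr = parse_formula(f"d({var()}) = 2", GRAPH)
        assert evaluator.formula_at(expr, 0)
        assert not evaluator.formula_at(expr, 1)

    def test_difference_needs_successor(self):
        trace = trace_of([3, 5])
        evaluator = Evaluator(trace, GRAPH)
        expr = parse_formula(f"d({var()}) = 2", GRAPH)
        with pytest.raises(HorizonError):
            evaluator.formula_at(expr, 1)

    def test_horizon_shortfall(self):
        trace = trace_of([1, 1, 1])
        with pytest.raises(HorizonError):
            evaluate(parse_formula(f"G[0,10] ({var()} > 0)", GRAPH),
                     trace, GRAPH)

    def test_missing_variable_errors(self):
        trace = fixtures.constant_trace("y", 1.0, SS, range(3))
        with pytest.raises(EvaluationError):
            evaluate(parse_formula(f"G[0,1] ({var()} > 0)", GRAPH),
                     trace, GRAPH)

    def test_carry_forward_mode(self):
        from mstmc.traces import (NumericObservation, Timepoint, Trace)
        trace = Trace([
            Timepoint(0.0, [NumericObservation("x", 7.0, SS)]),
            Timepoint(1.0, []),
        ])
        formula = parse_formula(f"G[0,1] ({var()} = 7)", GRAPH)
        assert evaluate(formula, trace, GRAPH, carry_forward=True)
        with pytest.raises(EvaluationError):
            evaluate(formula, trace, GRAPH)

    def test_division_by_zero(self):
        trace = trace_of([0])
        with pytest.raises(NumericError):
            evaluate(parse_formula(f"div(1, {var()}) > 0", GRAPH),
                     trace, GRAPH)

    def test_empty_collection_falsifies_comparison(self):
        trace = trace_of([1, 2])
        evaluator = Evaluator(trace, GRAPH)
        formula = parse_formula("avg(area(filter(regions))) > 0", GRAPH)
        assert evaluator.evaluate(formula) is False
        assert evaluator.warnings

    def test_count_of_empty_is_zero(self):
        trace = trace_of([1, 2])
        formula = parse_formula("count(area(filter(regions))) = 0", GRAPH)
        assert evaluate(formula, trace, GRAPH)

    def test_relative_origin(self):
        # First timestamp 100 is the temporal origin.
        trace = trace_of([5, 6, 7], times=[100, 101, 102])
        assert evaluate(parse_formula(f"F[0,2] ({var()} = 7)", GRAPH),
                        trace, GRAPH)


class TestRequiredHorizon:
    def test_plain_globally(self):
        assert required_horizon(
            parse_formula("G[0,95] (1 = 1)", GRAPH)) == 95

    def test_atom_only(self):
        assert required_horizon(parse_formula("1 = 1", GRAPH)) == 0

    def test_nesting_sums_upper_bounds(self):
        assert required_horizon(
            parse_formula("G[0,10] F[0,5] (1 = 1)", GRAPH)) == 15

    def test_temporal_collection_contributes(self):
        assert required_horizon(
            parse_formula(f"max([10, 30] {var()}) > 0", GRAPH)) == 30


# ---------------------------------------------------------------------------
# Oracle equivalence on random traces / formulas
# ---------------------------------------------------------------------------

def oracle_eval(f, xs, ts, i):
    """Independent direct-recursion semantics over a single variable x."""
    if isinstance(f, Comparison):
        ops = {"<": lambda a, b: a < b, "<=": lambda a, b: a <= b,
               "=": lambda a, b: math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-9),
               ">=": lambda a, b: a >= b, ">": lambda a, b: a > b}
        return ops[f.op](oracle_num(f.left, xs, ts, i),
                         oracle_num(f.right, xs, ts, i))
    if isinstance(f, Not):
        return not oracle_eval(f.operand, xs, ts, i)
    if isinstance(f, BoolOp):
        left = oracle_eval(f.left, xs, ts, i)
        right = oracle_eval(f.right, xs, ts, i)
        return {"and": left and right, "or": left or right,
                "=>": (not left) or right}[f.op]
    if isinstance(f, TemporalUnary):
        window = [j for j in range(len(ts))
                  if ts[i] + f.low <= ts[j] <= ts[i] + f.high]
        results = [oracle_eval(f.operand, xs, ts, j) for j in window]
        return all(results) if f.op == "G" else any(results)
    if isinstance(f, Until):
        for j in range(len(ts)):
            if not (ts[i] + f.low <= ts[j] <= ts[i] + f.high):
                continue
            if oracle_eval(f.right, xs, ts, j):
                prefix = [k for k in range(i, len(ts))
                          if k == i or ts[k] < ts[j]]
                if all(oracle_eval(f.left, xs, ts, k) for k in prefix):
                    return True
        return False
    raise TypeError(type(f))


def oracle_num(e, xs, ts, i):
    from mstmc.logic import (ArithFunction, Difference, Literal,
                             StatFunction, VariableRef)
    if isinstance(e, Literal):
        return e.value
    if isinstance(e, VariableRef):
        return xs[i]
    if isinstance(e, Difference):
        if i + 1 >= len(xs):
            raise HorizonError("no successor")
        return oracle_num(e.operand, xs, ts, i + 1) - oracle_num(
            e.operand, xs, ts, i)
    if isinstance(e, ArithFunction):
        args = [oracle_num(op, xs, ts, i) for op in e.operands]
        table = {"abs": lambda: abs(args[0]),
                 "floor": lambda: float(math.floor(args[0])),
                 "add": lambda: args[0] + args[1],
                 "subtract": lambda: args[0] - args[1],
                 "multiply": lambda: args[0] * args[1]}
        return table[e.name]()
    if isinstance(e, StatFunction):
        collection = e.collections[0]
        window = [j for j in range(len(ts))
                  if ts[i] + collection.low <= ts[j] <= ts[i] + collection.high]
        values = [oracle_num(collection.expression, xs, ts, j) for j in window]
        if e.name == "count":
            return float(len(values))
        if not values:
            raise _Empty()
        return {"avg": statistics.fmean, "min": min, "max": max,
                "sum": math.fsum}[e.name](values)
    raise TypeError(type(e))


class _Empty(Exception):
    pass


def _oracle_formula_safe(rng):
    """Random formula avoiding sqrt (domain) for oracle comparison."""
    formula = _random_formula(rng, rng.randrange(0, 4))

    def uses_sqrt(node):
        text = node.to_text()
        return "sqrt" in text
    return None if uses_sqrt(formula) else formula


class TestOracleEquivalence:
    def test_matches_direct_recursion_oracle(self):
        rng = random.Random(314)
        checked = 0
        while checked < 400:
            formula = _oracle_formula_safe(rng)
            if formula is None:
                continue
            xs = [float(rng.randrange(-3, 4)) for _ in range(10)]
            ts = list(range(10))
            trace = trace_of(xs, ts)
            evaluator = Evaluator(trace, GRAPH)
            try:
                expected = oracle_eval(formula, xs, ts, 0)
            except (_Empty, HorizonError):
                continue
            try:
                got = evaluator.formula_at(formula, 0)
            except HorizonError:
                continue
            assert got == expected, formula.to_text()
            checked += 1

    def test_globally_finally_duality(self):
        rng = random.Random(2718)
        for _ in range(200):
            inner = _random_formula(rng, 1)
            a = float(rng.randrange(0, 4))
            b = a + rng.randrange(0, 4)
            xs = [float(rng.randrange(-2, 3)) for _ in range(10)]
            trace = trace_of(xs)
            evaluator = Evaluator(trace, GRAPH)
            try:
                left = evaluator.formula_at(
                    Not(TemporalUnary("G", a, b, inner)), 0)
                right = evaluator.formula_at(
                    TemporalUnary("F", a, b, Not(inner)), 0)
            except (HorizonError, NumericError):
                continue
            assert left == right

    def test_globally_distributes_over_and(self):
        rng = random.Random(161)
        for _ in range(100):
            f1 = _random_formula(rng, 1)
            f2 = _random_formula(rng, 1)
            xs = [float(rng.randrange(-2, 3)) for _ in range(10)]
            trace = trace_of(xs)
            evaluator = Evaluator(trace, GRAPH)
            try:
                joint = evaluator.formula_at(
                    TemporalUnary("G", 0.0, 5.0, BoolOp("and", f1, f2)), 0)
                split = (evaluator.formula_at(
                    TemporalUnary("G", 0.0, 5.0, f1), 0)
                    and evaluator.formula_at(
                        TemporalUnary("G", 0.0, 5.0, f2), 0))
            except (HorizonError, NumericError):
                continue
            assert joint == split


# ---------------------------------------------------------------------------
# Statistical functions against textbook definitions
# ---------------------------------------------------------------------------

class TestStatisticalFunctions:
    DATA = [4.0, 1.0, 7.0, 1.0, 3.0, 9.0, 2.0]

    def check(self, name, expected, data=None, quantile=None):
        value = _apply_stat(name, [list(data or self.DATA)], quantile)
        assert value == pytest.approx(expected, rel=1e-12)

    def test_count(self):
        self.check("count", 7)

    def test_sum(self):
        self.check("sum", 27)

    def test_avg(self):
        self.check("avg", 27 / 7)

    def test_min_max(self):
        self.check("min", 1)
        self.check("max", 9)

    def test_median(self):
        self.check("median", 3)

    def test_mode_ties_to_smallest(self):
        self.check("mode", 1)
        self.check("mode", 2, data=[3, 3, 2, 2, 5])

    def test_product(self):
        self.check("product", 4 * 1 * 7 * 1 * 3 * 9 * 2)

    def test_stdev_sample(self):
        self.check("stdev", statistics.stdev(self.DATA))

    def test_var_sample(self):
        self.check("var", statistics.variance(self.DATA))

    def test_skew_biased(self):
        data = self.DATA
        mean = statistics.fmean(data)
        m2 = sum((x - mean) ** 2 for x in data) / len(data)
        m3 = sum((x - mean) ** 3 for x in data) / len(data)
        self.check("skew", m3 / m2 ** 1.5)

    def test_kurtosis_excess_biased(self):
        data = self.DATA
        mean = statistics.fmean(data)
        m2 = sum((x - mean) ** 2 for x in data) / len(data)
        m4 = sum((x - mean) ** 4 for x in data) / len(data)
        self.check("kurtosis", m4 / m2 ** 2 - 3.0)

    def test_geomean(self):
        self.check("geomean",
                   math.exp(statistics.fmean([math.log(x) for x in self.DATA])))

    def test_harmean(self):
        self.check("harmean",
                   len(self.DATA) / sum(1 / x for x in self.DATA))

    def test_covariance(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 4.0, 5.0, 4.0]
        expected = sum((x - 2.5) * (y - 3.75) for x, y in zip(a, b)) / 3
        value = _apply_stat("covariance", [a, b], None)
        assert value == pytest.approx(expected)

    def test_percentile_linear_interpolation(self):
        value = _apply_stat("percentile", [list(range(1, 101))], 90.0)
        assert value == pytest.approx(90.1)

    def test_quartile(self):
        value = _apply_stat("quartile", [list(range(1, 101))], 2.0)
        assert value == pytest.approx(50.5)

    def test_singleton_average(self):
        self.check("avg", 15, data=[15.0])


# ---------------------------------------------------------------------------
# Entity-set resolution
# ---------------------------------------------------------------------------

def _entity_trace(organism_graph):
    from mstmc.registry import default_registry
    registry = default_registry()
    base = {name: 0.5 if high == 1.0 else 5.0
            for name, (_, (low, high)) in registry.measures.items()}
    liver = dict(base, area=15.0)
    damaged = dict(base, area=3.0)
    hepatocyte = dict(base, area=20.0)
    tp = fixtures.entity_timepoint(0.0, [
        ("clusters", ScaleSubsystem("Organ", "Liver"), liver),
        ("regions", ScaleSubsystem("Tissue", "DamagedLiverTissue"), damaged),
        ("regions", ScaleSubsystem("Cellular", "Hepatocyte"), hepatocyte),
        ("regions", ScaleSubsystem("Organ", "Gut"), base),
    ])
    from mstmc.traces import Trace
    return Trace([tp])


class TestEntitySets:
    def test_subtree_filter(self, organism_graph):
        trace = _entity_trace(organism_graph)
        evaluator = Evaluator(trace, organism_graph)
        expr = parse_formula(
            "count(area(filter(regions, scaleAndSubsystem <= "
            "Tissue.DamagedLiverTissue))) = 2", organism_graph)
        assert evaluator.evaluate(expr)

    def test_measure_filter(self, organism_graph):
        trace = _entity_trace(organism_graph)
        evaluator = Evaluator(trace, organism_graph)
        expr = parse_formula(
            "count(area(filter(clusters, area > 10))) = 1", organism_graph)
        assert evaluator.evaluate(expr)

    def test_difference_with_self_is_empty(self, organism_graph):
        trace = _entity_trace(organism_graph)
        evaluator = Evaluator(trace, organism_graph)
        expr = parse_formula(
            "count(area(difference(filter(regions), filter(regions)))) = 0",
            organism_graph)
        assert evaluator.evaluate(expr)

    def test_union_and_intersection(self, organism_graph):
        trace = _entity_trace(organism_graph)
        evaluator = Evaluator(trace, organism_graph)
        assert evaluator.evaluate(parse_formula(
            "count(area(union(filter(regions, area > 10), "
            "filter(regions, area < 4)))) = 2", organism_graph))
        assert evaluator.evaluate(parse_formula(
            "count(area(intersection(filter(regions), "
            "filter(regions, area > 10)))) = 1", organism_graph))

    def test_strict_scale_filter(self, organism_graph):
        trace = _entity_trace(organism_graph)
        evaluator = Evaluator(trace, organism_graph)
        expr = parse_formula(
            "count(area(filter(regions, scaleAndSubsystem < "
            "Tissue.DamagedLiverTissue))) = 1", organism_graph)
        assert evaluator.evaluate(expr)
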