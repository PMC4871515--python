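"""Approximate probabilistic checking of ``P <cmp> theta [formula]`` queries.

Five algorithms decide a probabilistic query from a stream of per-trace
Boolean outcomes: an exact-binomial black-box test, a fixed-sample-size
estimator with a Chernoff-Hoeffding accuracy bound, Wald's sequential
probability ratio test, a Beta-posterior mean/variance estimator, and a
Bayes-factor sequential hypothesis test.  The checkers themselves are
deterministic given the outcome sequence; all stochasticity lives in
trace generation.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator

from scipy import stats as sps

from .errors import (GenerationError, MstmcError, ParameterError, SampleError)
from .logic import Evaluator, Query
from .magraph import MAGraph
from .registry import SpatialRegistry, default_registry
from .traces import Trace, read_mstml


@dataclass
class Verdict:
    """Checker output for one query."""

    holds: bool
    estimate: float | None
    n_total: int
    n_true: int
    n_false: int
    confidence_kind: str
    confidence_value: float | tuple
    extra: dict | None = None

    def __post_init__(self):
        assert self.n_true + self.n_false == self.n_total


class OutcomeProvider:
    """Stream of per-trace Boolean outcomes for one formula.

    Built either from a fixed list of traces/booleans or from a callable
    producing fresh traces on demand.
    """

    def __init__(self, source: Iterable | Callable[[], Trace],
                 query: Query | None = None,
                 graph: MAGraph | None = None,
                 carry_forward: bool = False):
        self._query = query
        self._graph = graph
        self._carry_forward = carry_forward
        if callable(source):
            self._iterator: Iterator = iter(source, None)
        else:
            self._iterator = iter(source)

    def _outcome(self, item) -> bool:
        if isinstance(item, bool):
            return item
        if isinstance(item, Trace):
            if self._query is None or self._graph is None:
                raise MstmcError("trace outcomes need a query and a graph")
            evaluator = Evaluator(item, self._graph, self._carry_forward)
            return bool(evaluator.evaluate(self._query.body))
        return bool(item)

    def __iter__(self) -> Iterator[bool]:
        for item in self._iterator:
            yield self._outcome(item)

    def take(self, n: int) -> list[bool]:
        outcomes = []
        for outcome in self:
            outcomes.append(outcome)
            if len(outcomes) == n:
                return outcomes
        raise SampleError(
            f"outcome provider exhausted after {len(outcomes)} of {n} samples")


def _as_provider(outcomes, query=None, graph=None) -> OutcomeProvider:
    if isinstance(outcomes, OutcomeProvider):
        return outcomes
    return OutcomeProvider(outcomes, query, graph)


def _direction_up(query: Query) -> bool:
    """True when the query claims the probability exceeds the threshold."""
    return query.comparator in (">", ">=")


# ---------------------------------------------------------------------------
# Probabilistic black-box checking
# ---------------------------------------------------------------------------

def blackbox_check(outcomes, q: Query) -> Verdict:
    """Exact-binomial black-box test over a fixed outcome list.

    For an upward claim (``P > theta``) the confidence (p-value) in the
    null hypothesis is ``P[Bin(n, theta) >= x]`` and in the alternative
    ``P[Bin(n, theta) <= x]``; the hypothesis with the lower p-value
    holds, ties resolved by the point estimate ``x / n``.
    """
    observed = list(_as_provider(outcomes, q))
    n = len(observed)
    if n == 0:
        raise SampleError("black-box checking needs at least one outcome")
    x = sum(observed)
    theta = q.threshold
    upper_tail = float(sps.binom.sf(x - 1, n, theta))   # P[X >= x]
    lower_tail = float(sps.binom.cdf(x, n, theta))      # P[X <= x]
    if _direction_up(q):
        pv_null, pv_alt = upper_tail, lower_tail
    else:
        pv_null, pv_alt = lower_tail, upper_tail
    estimate = x / n
    if pv_null == pv_alt:
        holds = q.compare(estimate)
    else:
        holds = pv_null < pv_alt
    return Verdict(holds, estimate, n, x, n - x, "p-value",
                   pv_null if holds else pv_alt,
                   extra={"p_value_null": pv_null, "p_value_alternative": pv_alt})


# ---------------------------------------------------------------------------
# Chernoff-Hoeffding bound based estimation
# ---------------------------------------------------------------------------

def chernoff_sample_size(epsilon: float, delta: float) -> int:
    """n = ceil((4 / epsilon^2) * ln(2 / delta))."""
    if not (0.0 < epsilon < 1.0) or not (0.0 < delta < 1.0):
        raise ParameterError("epsilon and delta must lie in (0, 1)")
    return math.ceil((4.0 / epsilon ** 2) * math.log(2.0 / delta))


def chernoff_check(provider, epsilon: float, delta: float, q: Query) -> Verdict:
    """Fixed-n estimator: with probability >= 1 - delta, |estimate - p| <= epsilon."""
    n = chernoff_sample_size(epsilon, delta)
    outcomes = _as_provider(provider, q).take(n)
    x = sum(outcomes)
    estimate = x / n
    return Verdict(q.compare(estimate), estimate, n, x, n - x,
                   "epsilon-delta", (epsilon, delta))


# ---------------------------------------------------------------------------
# Sequential probability ratio test
# ---------------------------------------------------------------------------

def sprt_check(provider, alpha: float, beta: float, half_width: float,
               q: Query) -> Verdict:
    """Wald's SPRT between p >= theta + half_width and p <= theta - half_width.

    The log likelihood ratio of the high-probability hypothesis against
    the low one is accumulated per outcome; crossing ``log((1-beta)/alpha)``
    accepts the high side, crossing ``log(beta/(1-alpha))`` the low side.
    The verdict is mapped back through the query's comparator.
    """
    if not (0.0 < alpha < 1.0) or not (0.0 < beta < 1.0):
        raise ParameterError("alpha and beta must lie in (0, 1)")
    theta = q.threshold
    if not (0.0 < half_width < min(theta, 1.0 - theta)):
        raise ParameterError(
            f"half_width must lie in (0, min(theta, 1 - theta)) = "
            f"(0, {min(theta, 1.0 - theta)})")
    p1, p0 = theta + half_width, theta - half_width
    accept_high = math.log((1.0 - beta) / alpha)
    accept_low = math.log(beta / (1.0 - alpha))
    log_true = math.log(p1 / p0)
    log_false = math.log((1.0 - p1) / (1.0 - p0))

    llr = 0.0
    n = x = 0
    for outcome in _as_provider(provider, q):
        n += 1
        x += outcome
        llr += log_true if outcome else log_false
        if llr >= accept_high:
            holds = _direction_up(q)
            return Verdict(holds, x / n, n, x, n - x, "log-likelihood-ratio",
                           llr, extra={"accepted": "high"})
        if llr <= accept_low:
            holds = not _direction_up(q)
            return Verdict(holds, x / n, n, x, n - x, "log-likelihood-ratio",
                           llr, extra={"accepted": "low"})
    raise SampleError(
        f"provider exhausted after {n} outcomes without an SPRT decision "
        f"(log likelihood ratio {llr:.4f})")


# ---------------------------------------------------------------------------
# Bayesian mean/variance estimation
# ---------------------------------------------------------------------------

def bayes_estimate_check(provider, prior_alpha: float, prior_beta: float,
                         variance_threshold: float, q: Query) -> Verdict:
    """Consume outcomes until the Beta-posterior variance drops below the
    threshold; the verdict compares the posterior mean with the query
    threshold."""
    if prior_alpha <= 0 or prior_beta <= 0:
        raise ParameterError("Beta prior parameters must be positive")
    if variance_threshold <= 0:
        raise ParameterError("variance threshold must be positive")

    def posterior(x, n):
        a = prior_alpha + x
        b = prior_beta + (n - x)
        mean = a / (a + b)
        variance = a * b / ((a + b) ** 2 * (a + b + 1))
        return mean, variance

    n = x = 0
    mean, variance = posterior(0, 0)
    if variance >= variance_threshold:
        for outcome in _as_provider(provider, q):
            n += 1
            x += outcome
            mean, variance = posterior(x, n)
            if variance < variance_threshold:
                break
        else:
            raise SampleError(
                f"provider exhausted after {n} outcomes with posterior "
                f"variance {variance:.3e} >= {variance_threshold:.3e}")
    return Verdict(q.compare(mean), mean, n, x, n - x,
                   "posterior-variance", variance)


# ---------------------------------------------------------------------------
# Bayes-factor hypothesis testing
# ---------------------------------------------------------------------------

def bayes_factor_check(provider, prior_alpha: float, prior_beta: float,
                       bf_threshold: float, q: Query,
                       prior_odds_normalized: bool = False) -> Verdict:
    """Sequential Bayes-factor test of the query against its complement.

    The confidence in the null hypothesis (the query itself) relative to
    the alternative is the posterior odds computed from the Beta
    posterior CDF at theta; sampling stops when it exceeds the threshold
    (holds) or drops below its reciprocal (does not hold).  With
    ``prior_odds_normalized`` the posterior odds are divided by the prior
    odds (the classical Bayes factor).
    """
    if prior_alpha <= 0 or prior_beta <= 0:
        raise ParameterError("Beta prior parameters must be positive")
    if bf_threshold <= 1.0:
        raise ParameterError("Bayes-factor threshold must exceed 1")
    theta = q.threshold

    def odds(x, n):
        cdf = float(sps.beta.cdf(theta, prior_alpha + x,
                                 prior_beta + (n - x)))
        null_mass = (1.0 - cdf) if _direction_up(q) else cdf
        alt_mass = 1.0 - null_mass
        if alt_mass == 0.0:
            return math.inf
        if null_mass == 0.0:
            return 0.0
        return null_mass / alt_mass

    prior = odds(0, 0)
    n = x = 0
    factor = prior
    for outcome in _as_provider(provider, q):
        n += 1
        x += outcome
        factor = odds(x, n)
        if prior_odds_normalized and prior not in (0.0, math.inf):
            factor = factor / prior
        if factor > bf_threshold or factor < 1.0 / bf_threshold:
            break
    else:
        raise SampleError(
            f"provider exhausted after {n} outcomes with Bayes factor "
            f"{factor:.4f}")
    a, b = prior_alpha + x, prior_beta + (n - x)
    return Verdict(factor > bf_threshold, a / (a + b), n, x, n - x,
                   "bayes-factor", factor)


# ---------------------------------------------------------------------------
# Trace sources and orchestration
# ---------------------------------------------------------------------------

def directory_traces(directory, registry: SpatialRegistry | None = None
                     ) -> list[Trace]:
    """Load every ``*.xml`` trace in a directory, lexicographic order.

    Architecture-graph files (``*.ma.xml``) are skipped so a directory can
    hold a complete experiment bundle.
    """
    registry = registry if registry is not None else default_registry()
    paths = sorted(path for path in Path(directory).glob("*.xml")
                   if not path.name.endswith(".ma.xml"))
    return [read_mstml(str(path), registry) for path in paths]


class GeneratorTraceSource:
    """On-demand traces from an external command.

    Each invocation runs ``command <output-directory>``; the command must
    create exactly one new trace file there.  A timeout or a missing new
    file aborts with a generation error.
    """

    def __init__(self, command: str, registry: SpatialRegistry | None = None,
                 timeout: float = 60.0, workdir=None):
        self.command = command
        self.registry = registry if registry is not None else default_registry()
        self.timeout = timeout
        self._workdir = Path(workdir) if workdir else Path(
            tempfile.mkdtemp(prefix="mstmc-gen-"))
        self._workdir.mkdir(parents=True, exist_ok=True)
        self._owns_workdir = workdir is None
        self._seen: set[Path] = set(self._workdir.glob("*.xml"))

    def __call__(self) -> Trace:
        deadline = time.monotonic() + self.timeout
        try:
            subprocess.run(
                f"{self.command} {self._workdir}", shell=True, check=True,
                timeout=self.timeout, capture_output=True)
        except subprocess.TimeoutExpired as exc:
            raise GenerationError(
                f"trace generator timed out after {self.timeout}s") from exc
        except subprocess.CalledProcessError as exc:
            raise GenerationError(
                f"trace generator failed with status {exc.returncode}: "
                f"{exc.stderr.decode(errors='replace')[:500]}") from exc
        while True:
            new = sorted(set(self._workdir.glob("*.xml")) - self._seen)
            if new:
                break
            if time.monotonic() > deadline:
                raise GenerationError("trace generator produced no new file")
            time.sleep(0.01)
        self._seen.update(new)
        return read_mstml(str(new[0]), self.registry)

    def stream(self):
        while True:
            yield self()

    def cleanup(self):
        if self._owns_workdir:
            shutil.rmtree(self._workdir, ignore_errors=True)


CHECKER_NAMES = ("blackbox", "chernoff", "sprt", "bayes-estimate",
                 "bayes-factor")


def run_checker(name: str, provider, q: Query, params: dict) -> Verdict:
    """Dispatch one named checker with its parameter dict."""
    if name == "blackbox":
        return blackbox_check(provider, q)
    if name == "chernoff":
        return chernoff_check(provider, params["epsilon"], params["delta"], q)
    if name == "sprt":
        return sprt_check(provider, params["alpha"], params["beta"],
                          params["half_width"], q)
    if name == "bayes-estimate":
        return bayes_estimate_check(provider, params["prior_alpha"],
                                    params["prior_beta"],
                                    params["variance_threshold"], q)
    if name == "bayes-factor":
        return bayes_factor_check(provider, params["prior_alpha"],
                                  params["prior_beta"],
                                  params["bf_threshold"], q)
    raise ParameterError(f"unknown checker {name!r}")


def run_model_checking(queries: list[Query], trace_source, graph: MAGraph,
                       checker: str, params: dict | None = None,
                       carry_forward: bool = False) -> list[tuple[Query, object]]:
    """Evaluate every statement over the same trace sequence.

    ``trace_source`` is either a list of traces (loaded once, reused
    across statements) or a callable yielding fresh traces.  Returns one
    ``(query, verdict-or-error)`` pair per statement; errors are captured
    per statement so the remaining statements still run.
    """
    params = params or {}
    results = []
    for query in queries:
        if callable(trace_source):
            provider = OutcomeProvider(trace_source, query, graph,
                                       carry_forward)
        else:
            provider = OutcomeProvider(list(trace_source), query, graph,
                                       carry_forward)
        try:
            verdict = run_checker(checker, provider, query, params)
        except MstmcError as exc:
            results.append((query, exc))
        else:
            results.append((query, verdict))
    return results
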