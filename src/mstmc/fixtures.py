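"""Self-contained test inputs: a toy stochastic cell model, synthetic
grids with known ground truth, and Bernoulli outcome streams.

The toy model is a single cell on a 2x2 grid that assimilates a nutrient
from its current position, converts it to energy, and spends energy to
move to a von Neumann neighbour.  Action weights are move 0.20, convert
0.30, assimilate 0.50, renormalized over the enabled actions; with no
enabled action the cell is dormant (terminal state).  The enumerator
uses exact rational arithmetic; the simulator uses floats and a seeded
generator.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .errors import PathError, ShapeSpecError
from .magraph import MAGraph, ScaleSubsystem
from .traces import (GridSnapshot, NumericObservation, SpatialEntityRecord,
                     Timepoint, Trace)

GRID_SIZE = 2

SS_NETWORK = ScaleSubsystem("Intracellular", "EnergyProductionReactionNetwork")
SS_CELL = ScaleSubsystem("Cellular", "Microorganism")
SS_MEDIA = ScaleSubsystem("Environment", "GrowthMedia")

ACTION_WEIGHTS = {"move": Fraction(2, 10), "convert": Fraction(3, 10),
                  "assimilate": Fraction(5, 10)}


def toy_ma_graph() -> MAGraph:
    """Three-vertex chain: growth media -> microorganism -> reaction network."""
    graph = MAGraph(SS_MEDIA)
    graph.add_edge(SS_MEDIA, SS_CELL)
    graph.add_edge(SS_CELL, SS_NETWORK)
    return graph


@dataclass(frozen=True)
class ToyState:
    cell_position: tuple[int, int]
    a_extracellular: tuple[tuple[int, ...], ...]  # 2x2 of {0, 1}
    a_intracellular: int
    energy: int

    def nutrient_at(self, position) -> int:
        return self.a_extracellular[position[0]][position[1]]


def initial_state() -> ToyState:
    """Cell in the lower-right corner, nutrient everywhere, no reserves."""
    return ToyState((GRID_SIZE - 1, GRID_SIZE - 1),
                    ((1, 1), (1, 1)), 0, 0)


def _neighbours(position):
    """In-bounds von Neumann neighbours, ordered by (col, row)."""
    row, col = position
    candidates = [(row, col - 1), (row - 1, col), (row, col + 1), (row + 1, col)]
    in_bounds = [(r, c) for r, c in candidates
                 if 0 <= r < GRID_SIZE and 0 <= c < GRID_SIZE]
    return sorted(in_bounds, key=lambda rc: (rc[1], rc[0]))


def _apply(state: ToyState, action: str, target=None) -> ToyState:
    grid = [list(row) for row in state.a_extracellular]
    if action == "assimilate":
        grid[state.cell_position[0]][state.cell_position[1]] = 0
        return ToyState(state.cell_position, tuple(map(tuple, grid)),
                        state.a_intracellular + 1, state.energy)
    if action == "convert":
        return ToyState(state.cell_position, state.a_extracellular,
                        state.a_intracellular - 1, state.energy + 1)
    return ToyState(target, state.a_extracellular,
                    state.a_intracellular, state.energy - 1)


def enabled_actions(state: ToyState) -> list[tuple[ToyState, Fraction]]:
    """Successor states with exact probabilities (renormalized weights).

    Move targets are listed in (col, row) order; an empty list marks a
    terminal (dormant) state.
    """
    enabled = []
    if state.energy > 0:
        enabled.append("move")
    if state.a_intracellular > 0:
        enabled.append("convert")
    if state.nutrient_at(state.cell_position) == 1:
        enabled.append("assimilate")
    if not enabled:
        return []
    total = sum(ACTION_WEIGHTS[a] for a in enabled)
    successors = []
    for action in enabled:
        weight = ACTION_WEIGHTS[action] / total
        if action == "move":
            targets = _neighbours(state.cell_position)
            share = weight / len(targets)
            for target in targets:
                successors.append((_apply(state, action, target), share))
        else:
            successors.append((_apply(state, action), weight))
    return successors


@dataclass
class TransitionSystem:
    states: list[ToyState]                      # breadth-first discovery order
    index: dict[ToyState, int]
    edges: dict[int, list[tuple[int, Fraction]]]

    @property
    def terminal_states(self) -> list[int]:
        return [i for i, _ in enumerate(self.states) if not self.edges[i]]

    def probability(self, i: int, j: int) -> Fraction:
        for target, p in self.edges[i]:
            if target == j:
                return p
        return Fraction(0)


def enumerate_state_space(start: ToyState | None = None) -> TransitionSystem:
    """Breadth-first closure of the reachable state space, exact rationals."""
    start = start if start is not None else initial_state()
    states = [start]
    index = {start: 0}
    edges: dict[int, list[tuple[int, Fraction]]] = {}
    queue = deque([start])
    while queue:
        state = queue.popleft()
        i = index[state]
        edges[i] = []
        for successor, probability in enabled_actions(state):
            if successor not in index:
                index[successor] = len(states)
                states.append(successor)
                queue.append(successor)
            edges[i].append((index[successor], probability))
    return TransitionSystem(states, index, edges)


def path_probability(ts: TransitionSystem, path: list[int]) -> Fraction:
    """Product of edge probabilities along a state-index sequence."""
    result = Fraction(1)
    for a, b in zip(path, path[1:]):
        p = ts.probability(a, b)
        if p == 0:
            raise PathError(f"no edge from state {a} to state {b}")
        result *= p
    return result


def simulate_toy(seed: int, max_steps: int = 20,
                 start: ToyState | None = None) -> Trace:
    """One seeded trajectory as a trace with timestamps 0, 1, 2, ...

    Numeric observations carry the nutrient reserve and energy at the
    reaction-network vertex; grid snapshots carry the cell position and
    the nutrient field (attached as detected-entity-free raw grids via
    :func:`toy_grids`, not as entity records).
    """
    rng = np.random.default_rng(seed)
    state = start if start is not None else initial_state()
    timepoints = []
    for step in range(max_steps + 1):
        timepoints.append(Timepoint(float(step), [
            NumericObservation("A_intracellular", float(state.a_intracellular),
                               SS_NETWORK),
            NumericObservation("Energy", float(state.energy), SS_NETWORK),
        ]))
        successors = enabled_actions(state)
        if not successors:
            break
        probabilities = np.array([float(p) for _, p in successors])
        choice = rng.choice(len(successors), p=probabilities / probabilities.sum())
        state = successors[choice][0]
    return Trace(timepoints)


def simulate_toy_states(seed: int, max_steps: int = 50,
                        start: ToyState | None = None) -> list[ToyState]:
    """The visited state sequence of one seeded trajectory."""
    rng = np.random.default_rng(seed)
    state = start if start is not None else initial_state()
    visited = [state]
    for _ in range(max_steps):
        successors = enabled_actions(state)
        if not successors:
            break
        probabilities = np.array([float(p) for _, p in successors])
        choice = rng.choice(len(successors), p=probabilities / probabilities.sum())
        state = successors[choice][0]
        visited.append(state)
    return visited


def toy_grids(state: ToyState, time: float = 0.0) -> list[GridSnapshot]:
    """Spatial frames of one toy state: cell occupancy and nutrient field."""
    cell = np.zeros((GRID_SIZE, GRID_SIZE))
    cell[state.cell_position] = 1.0
    nutrient = np.array(state.a_extracellular, dtype=float)
    return [GridSnapshot(cell, SS_CELL, "Cell", time),
            GridSnapshot(nutrient, SS_MEDIA, "A_extracellular", time)]


# ---------------------------------------------------------------------------
# Synthetic grids with known ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeTruth:
    kind: str
    area: int
    centroid: tuple[float, float]   # (row, col) of the occupied cells
    fill_value: float


def make_shape_grid(shape_specs, grid_shape=(32, 32),
                    scale_subsystem: ScaleSubsystem | None = None,
                    name: str = "field", time: float = 0.0
                    ) -> tuple[GridSnapshot, list[ShapeTruth]]:
    """Rasterize disjoint shapes onto a grid with exact expected values.

    Each spec is a dict with ``kind`` in {"rectangle", "disc", "ring"}:

    * rectangle: ``top``, ``left``, ``height``, ``width``
    * disc: ``center`` (row, col), ``radius``
    * ring: ``center``, ``radius``, ``inner_radius``

    plus optional ``value`` (default 1.0).  Overlap is rejected because
    the ground truth would be ambiguous.
    """
    grid = np.zeros(grid_shape)
    occupied = np.zeros(grid_shape, dtype=bool)
    truths = []
    rows, cols = np.indices(grid_shape)
    for spec in shape_specs:
        value = float(spec.get("value", 1.0))
        kind = spec["kind"]
        if kind == "rectangle":
            mask = np.zeros(grid_shape, dtype=bool)
            top, left = spec["top"], spec["left"]
            height, width = spec["height"], spec["width"]
            if top < 0 or left < 0 or top + height > grid_shape[0] \
                    or left + width > grid_shape[1]:
                raise ShapeSpecError(f"rectangle {spec} out of bounds")
            mask[top:top + height, left:left + width] = True
        elif kind in ("disc", "ring"):
            cr, cc = spec["center"]
            radius = spec["radius"]
            if cr - radius < 0 or cc - radius < 0 \
                    or cr + radius >= grid_shape[0] or cc + radius >= grid_shape[1]:
                raise ShapeSpecError(f"{kind} {spec} out of bounds")
            dist2 = (rows - cr) ** 2 + (cols - cc) ** 2
            mask = dist2 <= radius ** 2
            if kind == "ring":
                mask &= dist2 > spec["inner_radius"] ** 2
        else:
            raise ShapeSpecError(f"unknown shape kind {kind!r}")
        if (mask & occupied).any():
            raise ShapeSpecError(f"shape {spec} overlaps an earlier shape")
        occupied |= mask
        grid[mask] = value
        positions = np.argwhere(mask)
        centroid = positions.mean(axis=0)
        truths.append(ShapeTruth(kind, int(mask.sum()),
                                 (float(centroid[0]), float(centroid[1])),
                                 value))
    ss = scale_subsystem if scale_subsystem is not None else \
        ScaleSubsystem("Scale", "Subsystem")
    return GridSnapshot(grid, ss, name, time), truths


def bernoulli_outcomes(p: float, n: int, seed: int) -> list[bool]:
    """Reproducible i.i.d. Boolean stream with success probability ``p``."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return [bool(v) for v in rng.random(n) < p]


def bernoulli_stream(p: float, seed: int):
    """Endless reproducible Bernoulli generator (for sequential checkers)."""
    rng = np.random.default_rng(seed)
    while True:
        yield bool(rng.random() < p)


# ---------------------------------------------------------------------------
# Worked reference documents
# ---------------------------------------------------------------------------

def example_mstml_document() -> str:
    """A one-timepoint reference trace: one cluster and one numeric value."""
    return """<?xml version="1.0" encoding="utf-8"?>
<experiment>
  <timepoint value="1">
    <spatialEntity spatialType="cluster" scaleAndSubsystem="Organ.Liver">
      <clusteredness>0.01</clusteredness>
      <density>0.4</density>
      <area>15</area>
      <perimeter>28</perimeter>
      <distanceFromOrigin>81</distanceFromOrigin>
      <angle>10.5</angle>
      <triangleMeasure>0.5</triangleMeasure>
      <rectangleMeasure>1.0</rectangleMeasure>
      <circleMeasure>0.1</circleMeasure>
      <centroidX>703.4999</centroidX>
      <centroidY>118.087</centroidY>
    </spatialEntity>
    <numericStateVariable scaleAndSubsystem="Cellular.Hepatocyte">
      <name>dysfunction</name>
      <value>0.1</value>
    </numericStateVariable>
  </timepoint>
</experiment>
"""


def organ_ma_graph() -> MAGraph:
    """A small organism tree used by entity-filter tests.

    Organism.Human is the root with Organ.Gut, Organ.Lung and Organ.Liver
    children; the liver has a Tissue.DamagedLiverTissue child with two
    cellular children.
    """
    human = ScaleSubsystem("Organism", "Human")
    gut = ScaleSubsystem("Organ", "Gut")
    lung = ScaleSubsystem("Organ", "Lung")
    liver = ScaleSubsystem("Organ", "Liver")
    damaged = ScaleSubsystem("Tissue", "DamagedLiverTissue")
    hepatocyte = ScaleSubsystem("Cellular", "Hepatocyte")
    stellate = ScaleSubsystem("Cellular", "Stellate")
    graph = MAGraph(human)
    for child in (gut, lung, liver):
        graph.add_edge(human, child)
    graph.add_edge(liver, damaged)
    graph.add_edge(damaged, hepatocyte)
    graph.add_edge(damaged, stellate)
    return graph


def constant_trace(name: str, value: float, scale_subsystem: ScaleSubsystem,
                   times) -> Trace:
    """Trace holding one numeric variable constant over the given times."""
    return Trace([Timepoint(float(t), [
        NumericObservation(name, value, scale_subsystem)]) for t in times])


def numeric_trace(name: str, values, scale_subsystem: ScaleSubsystem,
                  times=None) -> Trace:
    """Trace of one numeric variable from an explicit value list."""
    values = list(values)
    times = list(times) if times is not None else list(range(len(values)))
    return Trace([Timepoint(float(t), [
        NumericObservation(name, float(v), scale_subsystem)])
        for t, v in zip(times, values)])


def entity_timepoint(time: float, specs) -> Timepoint:
    """Timepoint with entity records built from (type, ss, measures) specs."""
    return Timepoint(time, [], [
        SpatialEntityRecord.create(etype, ss, measures)
        for etype, ss, measures in specs])
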