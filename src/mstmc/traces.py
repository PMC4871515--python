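"""Timed multiscale traces: data model, MSTML XML and CSV ingestion.

A trace is an ordered sequence of timepoints.  Each timepoint carries
numeric observations and detected spatial entities, all annotated with
the ``scale.subsystem`` vertex they belong to.  The on-disk format is an
XML dialect (``experiment``/``timepoint``/``spatialEntity``/
``numericStateVariable``) whose element names are fixed; numeric values
round-trip through decimal text at 17 significant digits.
"""

from __future__ import annotations

import csv
import io
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

from .errors import (BindingError, FormatError, RangeError, RegistryError,
                     TraceOrderError)
from .magraph import MAGraph, ScaleSubsystem, _parse_xml
from .registry import SpatialRegistry, default_registry


@dataclass(frozen=True)
class NumericObservation:
    name: str
    value: float
    scale_subsystem: ScaleSubsystem

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise RangeError(f"observation {self.name}: value must be finite")


@dataclass(frozen=True)
class SpatialEntityRecord:
    """One detected spatial entity with its measure values."""

    entity_type: str
    scale_subsystem: ScaleSubsystem
    measures: tuple[tuple[str, float], ...]

    @classmethod
    def create(cls, entity_type, scale_subsystem, measures):
        if isinstance(measures, dict):
            measures = tuple(measures.items())
        return cls(entity_type, scale_subsystem, tuple(measures))

    @property
    def measure_map(self) -> dict[str, float]:
        return dict(self.measures)

    def measure(self, name: str) -> float:
        for key, value in self.measures:
            if key == name:
                return value
        raise RegistryError(f"entity has no measure {name!r}")

    def validate(self, registry: SpatialRegistry) -> None:
        registry.require_entity_type(self.entity_type)
        recorded = self.measure_map
        for name in registry.measures:
            if name not in recorded:
                raise FormatError(
                    f"{self.entity_type} entity missing measure {name!r}")
        for name, value in recorded.items():
            low, high = registry.measure_range(name)
            if not (low <= value <= high):
                raise RangeError(
                    f"measure {name}={value} outside range [{low}, {high}]")


@dataclass
class Timepoint:
    time: float
    numeric: list[NumericObservation] = field(default_factory=list)
    entities: list[SpatialEntityRecord] = field(default_factory=list)

    def __post_init__(self):
        if not math.isfinite(self.time) or self.time < 0:
            raise RangeError(f"timestamp {self.time} must be finite and >= 0")

    def lookup(self, name: str, scale_subsystem: ScaleSubsystem):
        for obs in self.numeric:
            if obs.name == name and obs.scale_subsystem == scale_subsystem:
                return obs.value
        return None


@dataclass
class Trace:
    timepoints: list[Timepoint] = field(default_factory=list)

    def __post_init__(self):
        times = [tp.time for tp in self.timepoints]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise TraceOrderError("timestamps must be strictly increasing")

    def __len__(self):
        return len(self.timepoints)

    @property
    def times(self) -> list[float]:
        return [tp.time for tp in self.timepoints]

    @property
    def duration(self) -> float:
        return self.timepoints[-1].time - self.timepoints[0].time


@dataclass
class GridSnapshot:
    """A single spatial-state-variable frame: an m x n array in [0, 1]."""

    values: np.ndarray
    scale_subsystem: ScaleSubsystem
    spatial_variable_name: str
    time: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise FormatError("grid must be a 2D array with m, n >= 1")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise RangeError("grid values must lie in [0, 1]; pre-normalize")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# MSTML reading / writing
# ---------------------------------------------------------------------------

def read_mstml(source, registry: SpatialRegistry | None = None) -> Trace:
    """Parse an MSTML document into a :class:`Trace`.

    ``registry`` controls which entity types and measure elements are
    accepted; defaults to the built-in regions/clusters registry.
    """
    registry = registry if registry is not None else default_registry()
    root = _parse_xml(source)
    if root.tag != "experiment":
        raise FormatError(f"expected root element 'experiment', got {root.tag!r}")
    timepoints = []
    previous_time = None
    for tp_elem in root:
        if tp_elem.tag != "timepoint":
            raise FormatError(f"unexpected element {tp_elem.tag!r}")
        time = _parse_number(tp_elem.attrib.get("value"), "timepoint value")
        if previous_time is not None and time <= previous_time:
            raise TraceOrderError(
                f"timepoint {time} not after previous {previous_time}")
        previous_time = time
        numeric, entities = [], []
        for child in tp_elem:
            if child.tag == "numericStateVariable":
                numeric.append(_read_numeric(child))
            elif child.tag == "spatialEntity":
                entities.append(_read_entity(child, registry))
            else:
                raise FormatError(f"unexpected element {child.tag!r}")
        timepoints.append(Timepoint(time, numeric, entities))
    return Trace(timepoints)


def _read_numeric(elem) -> NumericObservation:
    ss = _parse_scale_subsystem(elem)
    name_elem = elem.find("name")
    value_elem = elem.find("value")
    if name_elem is None or value_elem is None:
        raise FormatError("numericStateVariable needs <name> and <value>")
    value = _parse_number(value_elem.text, f"value of {name_elem.text}")
    return NumericObservation(name_elem.text.strip(), value, ss)


def _read_entity(elem, registry: SpatialRegistry) -> SpatialEntityRecord:
    entity_type = elem.attrib.get("spatialType")
    if not entity_type:
        raise FormatError("spatialEntity missing 'spatialType'")
    if entity_type not in registry.entity_types:
        # Documents may use the singular form (spatialType="cluster").
        if entity_type + "s" in registry.entity_types:
            entity_type += "s"
        else:
            raise FormatError(
                f"entity type {entity_type!r} not in active registry")
    ss = _parse_scale_subsystem(elem)
    measures = []
    for child in elem:
        if child.tag not in registry.measures:
            raise FormatError(
                f"measure element {child.tag!r} not in active registry")
        measures.append((child.tag,
                         _parse_number(child.text, f"measure {child.tag}")))
    record = SpatialEntityRecord.create(entity_type, ss, measures)
    record.validate(registry)
    return record


def _parse_scale_subsystem(elem) -> ScaleSubsystem:
    raw = elem.attrib.get("scaleAndSubsystem")
    if raw is None:
        raise FormatError(f"{elem.tag} missing 'scaleAndSubsystem'")
    return ScaleSubsystem.parse(raw)


def _parse_number(text, what) -> float:
    try:
        value = float(text)
    except (TypeError, ValueError):
        raise FormatError(f"non-numeric {what}: {text!r}") from None
    if not math.isfinite(value):
        raise FormatError(f"non-finite {what}: {text!r}")
    return value


def write_mstml(trace: Trace) -> str:
    """Serialize a trace to MSTML text (inverse of :func:`read_mstml`)."""
    root = ET.Element("experiment")
    for tp in trace.timepoints:
        tp_elem = ET.SubElement(root, "timepoint",
                                {"value": _format_number(tp.time)})
        for entity in tp.entities:
            e = ET.SubElement(tp_elem, "spatialEntity", {
                "spatialType": entity.entity_type,
                "scaleAndSubsystem": str(entity.scale_subsystem)})
            for name, value in entity.measures:
                ET.SubElement(e, name).text = _format_number(value)
        for obs in tp.numeric:
            n = ET.SubElement(tp_elem, "numericStateVariable", {
                "scaleAndSubsystem": str(obs.scale_subsystem)})
            ET.SubElement(n, "name").text = obs.name
            ET.SubElement(n, "value").text = _format_number(obs.value)
    ET.indent(root, space="  ")
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def _format_number(value: float) -> str:
    # 17 significant digits: lossless for IEEE doubles.
    if float(value).is_integer() and abs(value) < 1e16:
        return str(int(value))
    return format(value, ".17g")


# ---------------------------------------------------------------------------
# CSV ingestion of raw simulator output
# ---------------------------------------------------------------------------

def read_numeric_csv(source, ma: MAGraph) -> Trace:
    """Read a numeric time-series CSV into a (spatial-entity-free) trace.

    Header must be ``time, name@scale.subsystem, ...``; one row per
    timepoint.  Every referenced ``scale.subsystem`` must be a vertex of
    ``ma``.
    """
    rows = _read_csv_rows(source)
    if not rows:
        raise FormatError("numeric CSV needs a header row")
    header = [cell.strip() for cell in rows[0]]
    if not header or header[0] != "time":
        raise FormatError("first CSV column must be 'time'")
    columns = []
    for cell in header[1:]:
        name, sep, ss_text = cell.partition("@")
        if not sep or not name:
            raise FormatError(f"column {cell!r} is not 'name@scale.subsystem'")
        ss = ScaleSubsystem.parse(ss_text)
        if ss not in ma:
            raise BindingError(f"column {cell!r}: unknown vertex {ss}")
        columns.append((name, ss))
    timepoints = []
    for row in rows[1:]:
        if len(row) != len(header):
            raise FormatError(f"ragged row {row!r}")
        time = _parse_number(row[0], "time")
        numeric = [NumericObservation(name, _parse_number(cell, f"column {name}"), ss)
                   for (name, ss), cell in zip(columns, row[1:])]
        timepoints.append(Timepoint(time, numeric))
    return Trace(timepoints)


def read_grid_csv(source, scale_subsystem: ScaleSubsystem,
                  spatial_variable_name: str = "value",
                  time: float = 0.0) -> GridSnapshot:
    """Read one grid snapshot; file row 0 is the top grid row."""
    rows = _read_csv_rows(source)
    if not rows:
        raise FormatError("grid CSV is empty")
    width = len(rows[0])
    body = []
    for row in rows:
        if len(row) != width:
            raise FormatError(f"ragged row {row!r}")
        body.append([_parse_number(cell, "grid value") for cell in row])
    return GridSnapshot(np.array(body, dtype=float), scale_subsystem,
                        spatial_variable_name, time)


def _read_csv_rows(source) -> list[list[str]]:
    if isinstance(source, str) and ("\n" in source or "," in source):
        handle = io.StringIO(source)
    elif hasattr(source, "read"):
        handle = source
    else:
        handle = open(source, newline="")
    with handle:
        return [row for row in csv.reader(handle) if row]
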