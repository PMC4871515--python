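"""Registry of spatial entity types and spatial measures.

The detection procedures and measure formulas are fixed code, but *which*
entity types and measures a given analysis uses is configuration: a
registry instance declares the active names, the procedure each name is
bound to and the valid value range of each measure.  Trace readers
validate recorded entities against the active registry, so swapping the
configuration re-instantiates the whole checking pipeline without code
changes.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .errors import ConfigError, FormatError, RegistryError

#: Built-in measure procedures and their value ranges.
BUILTIN_MEASURES: dict[str, tuple[float, float]] = {
    "clusteredness": (0.0, 1.0),
    "density": (0.0, 1.0),
    "area": (0.0, math.inf),
    "perimeter": (0.0, math.inf),
    "distanceFromOrigin": (0.0, math.inf),
    "angle": (0.0, 360.0),
    "triangleMeasure": (0.0, 1.0),
    "rectangleMeasure": (0.0, 1.0),
    "circleMeasure": (0.0, 1.0),
    "centroidX": (0.0, math.inf),
    "centroidY": (0.0, math.inf),
}

#: Built-in entity detection procedures.
BUILTIN_ENTITY_TYPES = ("regions", "clusters")


@dataclass
class SpatialRegistry:
    """Active entity types and measures.

    ``entity_types`` maps an entity-type name to a detection-procedure
    identifier; ``measures`` maps a measure name to a
    ``(procedure identifier, (low, high))`` pair.  Procedure identifiers
    must name a built-in procedure or one registered via
    :meth:`register_procedure`.
    """

    entity_types: dict[str, str] = field(default_factory=dict)
    measures: dict[str, tuple[str, tuple[float, float]]] = field(
        default_factory=dict)
    custom_procedures: dict[str, object] = field(default_factory=dict)

    def known_procedures(self) -> set[str]:
        return (set(BUILTIN_MEASURES) | set(BUILTIN_ENTITY_TYPES)
                | set(self.custom_procedures))

    def register_procedure(self, identifier: str, procedure) -> None:
        if identifier in self.known_procedures():
            raise RegistryError(f"procedure {identifier!r} already registered")
        self.custom_procedures[identifier] = procedure

    def measure_range(self, name: str) -> tuple[float, float]:
        try:
            return self.measures[name][1]
        except KeyError:
            raise RegistryError(f"unregistered measure {name!r}") from None

    def require_entity_type(self, name: str) -> None:
        if name not in self.entity_types:
            raise RegistryError(f"unregistered entity type {name!r}")

    def require_measure(self, name: str) -> None:
        if name not in self.measures:
            raise RegistryError(f"unregistered measure {name!r}")


def default_registry() -> SpatialRegistry:
    """Registry with regions + clusters and the eleven standard measures."""
    return SpatialRegistry(
        entity_types={name: name for name in BUILTIN_ENTITY_TYPES},
        measures={name: (name, rng) for name, rng in BUILTIN_MEASURES.items()},
    )


def load_spatial_config(source) -> SpatialRegistry:
    """Build a registry from a configuration XML document.

    Format::

        <spatialConfiguration>
          <entityType name="regions" procedure="regions"/>
          <measure name="area" procedure="area" min="0" max="INF"/>
        </spatialConfiguration>
    """
    from .magraph import _parse_xml  # shared tolerant XML entry point

    root = _parse_xml(source)
    if root.tag != "spatialConfiguration":
        raise FormatError(
            f"expected root element 'spatialConfiguration', got {root.tag!r}")
    registry = SpatialRegistry()
    for elem in root:
        name = elem.attrib.get("name")
        procedure = elem.attrib.get("procedure", name)
        if not name:
            raise ConfigError(f"element {elem.tag!r} missing 'name'")
        if procedure not in registry.known_procedures():
            raise ConfigError(f"unknown procedure identifier {procedure!r}")
        if elem.tag == "entityType":
            if name in registry.entity_types:
                raise ConfigError(f"duplicate entity type {name!r}")
            registry.entity_types[name] = procedure
        elif elem.tag == "measure":
            if name in registry.measures:
                raise ConfigError(f"duplicate measure {name!r}")
            low = _parse_bound(elem.attrib.get("min", "-INF"))
            high = _parse_bound(elem.attrib.get("max", "INF"))
            if low > high:
                raise ConfigError(
                    f"measure {name!r}: lower bound {low} > upper bound {high}")
            registry.measures[name] = (procedure, (low, high))
        else:
            raise FormatError(f"unexpected element {elem.tag!r}")
    return registry


def serialize_spatial_config(registry: SpatialRegistry) -> str:
    root = ET.Element("spatialConfiguration")
    for name, procedure in registry.entity_types.items():
        ET.SubElement(root, "entityType", {"name": name, "procedure": procedure})
    for name, (procedure, (low, high)) in registry.measures.items():
        ET.SubElement(root, "measure", {
            "name": name, "procedure": procedure,
            "min": _format_bound(low), "max": _format_bound(high)})
    ET.indent(root, space="  ")
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def _parse_bound(text: str) -> float:
    if text == "INF":
        return math.inf
    if text == "-INF":
        return -math.inf
    try:
        return float(text)
    except ValueError as exc:
        raise ConfigError(f"invalid bound {text!r}") from exc


def _format_bound(value: float) -> str:
    if value == math.inf:
        return "INF"
    if value == -math.inf:
        return "-INF"
    return repr(value)
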