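"""Multiscale architecture graph: a rooted tree of (scale, subsystem) vertices.

The graph encodes how a coarse-grained subsystem decomposes into
finer-grained ones.  Two partial orders are derived from it: ``a <= b``
holds when the unique root-to-``a`` path passes through ``b`` (``a`` is
``b`` or one of its descendants), and ``a < b`` is the strict variant.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Iterable

from .errors import FormatError, GraphLookupError, StructureError

_TOKEN_RE = re.compile(r"^[^\s.]+$")


@dataclass(frozen=True, order=True)
class ScaleSubsystem:
    """A (scale, subsystem) pair, rendered as ``scale.subsystem``."""

    scale: str
    subsystem: str

    def __post_init__(self):
        for token in (self.scale, self.subsystem):
            if not token or not _TOKEN_RE.match(token):
                raise FormatError(
                    f"invalid scale/subsystem token {token!r}: tokens must be "
                    "non-empty and contain no whitespace or '.'"
                )

    def __str__(self):
        return f"{self.scale}.{self.subsystem}"

    @classmethod
    def parse(cls, text: str) -> "ScaleSubsystem":
        parts = text.split(".")
        if len(parts) != 2:
            raise FormatError(f"expected 'scale.subsystem', got {text!r}")
        return cls(parts[0], parts[1])


class MAGraph:
    """Rooted directed tree over :class:`ScaleSubsystem` vertices."""

    def __init__(self, root: ScaleSubsystem,
                 edges: Iterable[tuple[ScaleSubsystem, ScaleSubsystem]] = ()):
        self.root = root
        self._parent: dict[ScaleSubsystem, ScaleSubsystem] = {}
        self._children: dict[ScaleSubsystem, list[ScaleSubsystem]] = {root: []}
        for parent, child in edges:
            self.add_edge(parent, child)

    # -- construction -------------------------------------------------

    def add_edge(self, parent: ScaleSubsystem, child: ScaleSubsystem) -> None:
        if parent not in self._children:
            raise StructureError(f"parent {parent} not in graph")
        if child in self._children:
            raise StructureError(
                f"vertex {child} already present (duplicate or second parent)")
        self._parent[child] = parent
        self._children[parent].append(child)
        self._children[child] = []

    # -- queries ------------------------------------------------------

    @property
    def vertices(self) -> list[ScaleSubsystem]:
        """All vertices in pre-order (document order for loaded graphs)."""
        return list(self._iter_preorder(self.root))

    @property
    def edges(self) -> list[tuple[ScaleSubsystem, ScaleSubsystem]]:
        return [(self._parent[v], v) for v in self.vertices if v != self.root]

    def __contains__(self, v: ScaleSubsystem) -> bool:
        return v in self._children

    def __len__(self) -> int:
        return len(self._children)

    def children(self, v: ScaleSubsystem) -> list[ScaleSubsystem]:
        self._require(v)
        return list(self._children[v])

    def parent(self, v: ScaleSubsystem) -> ScaleSubsystem | None:
        self._require(v)
        return self._parent.get(v)

    def _require(self, v: ScaleSubsystem) -> None:
        if v not in self._children:
            raise GraphLookupError(f"unknown vertex {v}")

    def _iter_preorder(self, v: ScaleSubsystem):
        yield v
        for child in self._children[v]:
            yield from self._iter_preorder(child)

    # -- partial orders -----------------------------------------------

    def precedes_or_equal(self, a: ScaleSubsystem, b: ScaleSubsystem) -> bool:
        """True iff ``a`` equals ``b`` or lies below it in the tree."""
        self._require(a)
        self._require(b)
        node: ScaleSubsystem | None = a
        while node is not None:
            if node == b:
                return True
            node = self._parent.get(node)
        return False

    def precedes(self, a: ScaleSubsystem, b: ScaleSubsystem) -> bool:
        """Strict variant of :meth:`precedes_or_equal`."""
        return a != b and self.precedes_or_equal(a, b)

    def select_vertices(self, relation: str,
                        ref: ScaleSubsystem) -> list[ScaleSubsystem]:
        """Vertices ``v`` with ``v relation ref``; pre-order, deterministic.

        ``relation`` is one of ``"="``, ``"<"``, ``"<="``.
        """
        self._require(ref)
        if relation == "=":
            return [ref]
        if relation == "<":
            return [v for v in self.vertices if self.precedes(v, ref)]
        if relation == "<=":
            return [v for v in self.vertices if self.precedes_or_equal(v, ref)]
        raise ValueError(f"unknown relation {relation!r}")


def load_ma_graph(source) -> MAGraph:
    """Parse an architecture graph XML document (path, file or string).

    The dialect is ``<multiscaleArchitecture rootScale=.. rootSubsystem=..>``
    with nested ``<vertex scale=.. subsystem=..>`` elements; nesting encodes
    the tree edges, so cycles and multiple roots are impossible to express,
    but duplicate vertices are still rejected.
    """
    root_elem = _parse_xml(source)
    if root_elem.tag != "multiscaleArchitecture":
        raise FormatError(
            f"expected root element 'multiscaleArchitecture', got {root_elem.tag!r}")
    try:
        root = ScaleSubsystem(root_elem.attrib["rootScale"],
                              root_elem.attrib["rootSubsystem"])
    except KeyError as exc:
        raise FormatError(f"missing attribute {exc} on root element") from exc
    graph = MAGraph(root)

    def walk(elem, parent_vertex):
        for child in elem:
            if child.tag != "vertex":
                raise FormatError(f"unexpected element {child.tag!r}")
            try:
                v = ScaleSubsystem(child.attrib["scale"], child.attrib["subsystem"])
            except KeyError as exc:
                raise FormatError(f"missing attribute {exc} on vertex") from exc
            if v in graph:
                raise FormatError(f"duplicate vertex {v}")
            graph.add_edge(parent_vertex, v)
            walk(child, v)

    walk(root_elem, root)
    return graph


def serialize_ma_graph(graph: MAGraph) -> str:
    """Emit the XML dialect read by :func:`load_ma_graph` (UTF-8, 2-space indent)."""
    root = ET.Element("multiscaleArchitecture", {
        "rootScale": graph.root.scale, "rootSubsystem": graph.root.subsystem})

    def emit(parent_elem, vertex):
        for child in graph.children(vertex):
            elem = ET.SubElement(parent_elem, "vertex", {
                "scale": child.scale, "subsystem": child.subsystem})
            emit(elem, child)

    emit(root, graph.root)
    ET.indent(root, space="  ")
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def _parse_xml(source) -> ET.Element:
    if isinstance(source, str) and source.lstrip().startswith("<"):
        try:
            return ET.fromstring(source)
        except ET.ParseError as exc:
            raise FormatError(f"malformed XML: {exc}") from exc
    try:
        return ET.parse(source).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"malformed XML: {exc}") from exc
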