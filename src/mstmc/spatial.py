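"""Detection of emergent spatial entities in grid snapshots.

Regions are 8-connected components of grid positions whose value reaches
a threshold and whose size exceeds a cutoff.  Clusters are maximal
density-reachable sets of regions under DBSCAN with the Euclidean
distance between region centroids.  Every detected entity is described
by the measures active in a :class:`~mstmc.registry.SpatialRegistry`.

Geometry conventions (fixed so tests can be exact):

* coordinates are (row, col), 0-based; ``centroidX`` is the column and
  ``centroidY`` the row coordinate;
* the outer contour of a region passes through pixel centers (Moore
  boundary trace); a single-pixel region degenerates to a point with
  perimeter 0;
* the centre of the spatial domain is ((m-1)/2, (n-1)/2);
* the shape measures divide the entity hull area by the area of the
  minimum-area enclosing triangle / rotated rectangle / circle; an
  entity with a degenerate (zero-area) hull scores 1 on all three;
* cluster clusteredness is 1 minus the mean pairwise distance between
  occupied positions normalized by the grid diagonal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint, Point

from .errors import RegistryError
from .registry import SpatialRegistry
from .traces import GridSnapshot, SpatialEntityRecord

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class RegionParams:
    threshold: float
    min_size: int = 1

    def __post_init__(self):
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


@dataclass(frozen=True)
class ClusterParams:
    eps_distance: float
    min_regions: int = 1

    def __post_init__(self):
        if self.eps_distance <= 0:
            raise ValueError("eps_distance must be > 0")
        if self.min_regions < 1:
            raise ValueError("min_regions must be >= 1")


@dataclass
class DetectedRegion:
    mask: np.ndarray
    contour: list[tuple[int, int]]
    measures: dict[str, float] = field(default_factory=dict)

    @property
    def positions(self) -> np.ndarray:
        return np.argwhere(self.mask)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        """(row, col) of the geometric centre of the distinct contour points."""
        pts = np.array(sorted(set(self.contour)), dtype=float)
        centre = pts.mean(axis=0)
        return float(centre[0]), float(centre[1])


@dataclass
class DetectedCluster:
    member_regions: list[DetectedRegion]
    measures: dict[str, float] = field(default_factory=dict)

    @property
    def positions(self) -> np.ndarray:
        return np.concatenate([r.positions for r in self.member_regions])

    @property
    def hull(self):
        """Convex hull (shapely geometry, x=col/y=row) of member positions."""
        return MultiPoint([(c, r) for r, c in self.positions]).convex_hull


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_regions(grid: GridSnapshot, p: RegionParams) -> list[DetectedRegion]:
    """8-connected components of above-threshold positions, size > min_size."""
    above = grid.values >= p.threshold
    labels, count = ndimage.label(above, structure=_EIGHT)
    regions = []
    for index in range(1, count + 1):
        mask = labels == index
        if int(mask.sum()) <= p.min_size:  # strict: size must exceed cutoff
            continue
        regions.append(DetectedRegion(mask, trace_contour(mask)))
    regions.sort(key=lambda r: tuple(min(map(tuple, r.positions))))
    return regions


def detect_clusters(regions: list[DetectedRegion], p: ClusterParams,
                    return_noise: bool = False):
    """DBSCAN over region centroids; deterministic index-order semantics.

    A region is *core* when at least ``min_regions`` regions (itself
    included) lie within ``eps_distance`` of its centroid.  Clusters are
    the density-reachability closures of cores; a non-core region within
    reach of several clusters joins the cluster of the earliest-indexed
    core that reaches it.  Unreachable non-core regions are noise.
    """
    n = len(regions)
    if n == 0:
        return ([], []) if return_noise else []
    centroids = np.array([r.centroid for r in regions])
    diff = centroids[:, None, :] - centroids[None, :, :]
    within = np.hypot(diff[..., 0], diff[..., 1]) <= p.eps_distance
    neighbour_counts = within.sum(axis=1)
    core = neighbour_counts >= p.min_regions

    assignment = [-1] * n
    cluster_members: list[list[int]] = []
    for i in range(n):
        if not core[i] or assignment[i] != -1:
            continue
        members = []
        queue = [i]
        assignment[i] = len(cluster_members)
        while queue:
            j = queue.pop(0)
            members.append(j)
            if not core[j]:
                continue
            for k in np.flatnonzero(within[j]):
                if assignment[k] == -1:
                    assignment[k] = assignment[i]
                    queue.append(int(k))
        cluster_members.append(sorted(members))
    # Re-resolve border regions to the earliest-indexed core that reaches them.
    for j in range(n):
        if core[j]:
            continue
        reaching = [i for i in range(n) if core[i] and within[i][j]]
        if reaching:
            target = assignment[reaching[0]]
            if assignment[j] != target:
                cluster_members[assignment[j]].remove(j)
                cluster_members[target].append(j)
                cluster_members[target].sort()
                assignment[j] = target

    cluster_members.sort(key=lambda members: members[0])
    clusters = [DetectedCluster([regions[j] for j in members])
                for members in cluster_members if members]
    noise = [regions[j] for j in range(n) if assignment[j] == -1]
    return (clusters, noise) if return_noise else clusters


# ---------------------------------------------------------------------------
# Contour tracing (Moore boundary following through pixel centers)
# ---------------------------------------------------------------------------

# Clockwise Moore neighbourhood starting west, in (row, col) offsets.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_contour(mask: np.ndarray) -> list[tuple[int, int]]:
    """Ordered outer-boundary pixel centers of one 8-connected component."""
    positions = np.argwhere(mask)
    if len(positions) == 0:
        return []
    start = tuple(min(map(tuple, positions)))
    if len(positions) == 1:
        return [start]
    in_mask = {tuple(p) for p in map(tuple, positions)}
    contour = [start]
    # Entered the start "from the west" (outside, since start is the
    # lexicographic minimum).
    current, direction = start, 0
    first_move = None
    for _ in range(8 * len(positions) + 8):
        for step in range(8):
            d = (direction + step) % 8
            nxt = (current[0] + _MOORE[d][0], current[1] + _MOORE[d][1])
            if nxt in in_mask:
                if first_move is None:
                    first_move = (current, d)
                elif (current, d) == first_move:
                    return contour
                contour.append(nxt)
                current = nxt
                # Continue scanning from the neighbour before the one we
                # came from (backtrack rule).
                direction = (d + 5) % 8
                break
        else:  # isolated pixel inside an 8-connected mask: cannot happen
            return contour
    return contour  # safety cap; unreachable for valid masks


# ---------------------------------------------------------------------------
# Measures
# ---------------------------------------------------------------------------

def compute_measures(entity, grid: GridSnapshot,
                     registry: SpatialRegistry) -> dict[str, float]:
    """Evaluate every registered measure for a detected entity."""
    geo = _entity_geometry(entity, grid)
    values = {}
    for name, (procedure, (low, high)) in registry.measures.items():
        if procedure in _BUILTIN_MEASURES:
            value = _BUILTIN_MEASURES[procedure](entity, grid, geo)
        elif procedure in registry.custom_procedures:
            value = float(registry.custom_procedures[procedure](entity, grid))
        else:
            raise RegistryError(f"unknown measure procedure {procedure!r}")
        values[name] = min(max(value, low), high) if math.isfinite(value) else value
    return values


class _Geometry:
    """Shared per-entity geometry (shapely objects use x=col, y=row)."""

    def __init__(self, outline_points, positions, grid_shape):
        self.outline = np.asarray(outline_points, dtype=float)  # (row, col)
        self.positions = np.asarray(positions)
        self.centre = ((grid_shape[0] - 1) / 2.0, (grid_shape[1] - 1) / 2.0)
        self.centre_point = Point(self.centre[1], self.centre[0])
        self.hull = MultiPoint(
            [(c, r) for r, c in self.outline]).convex_hull
        self.hull_area = getattr(self.hull, "area", 0.0)


def _entity_geometry(entity, grid) -> _Geometry:
    if isinstance(entity, DetectedRegion):
        outline = sorted(set(entity.contour))
        return _Geometry(outline, entity.positions, grid.shape)
    if isinstance(entity, DetectedCluster):
        positions = entity.positions
        return _Geometry(positions, positions, grid.shape)
    raise TypeError(f"unsupported entity {type(entity).__name__}")


def _m_area(entity, grid, geo):
    return float(len(geo.positions))


def _m_density(entity, grid, geo):
    rows, cols = geo.positions[:, 0], geo.positions[:, 1]
    return float(grid.values[rows, cols].mean())


def _m_perimeter(entity, grid, geo):
    if isinstance(entity, DetectedRegion):
        pts = np.asarray(entity.contour, dtype=float)
        if len(pts) < 2:
            return 0.0
        closed = np.vstack([pts, pts[:1]])
        return float(np.hypot(*np.diff(closed, axis=0).T).sum())
    return float(geo.hull.length) if geo.hull.geom_type == "Polygon" else (
        2.0 * float(geo.hull.length))


def _m_distance_from_origin(entity, grid, geo):
    if isinstance(entity, DetectedRegion):
        deltas = geo.outline - np.array(geo.centre)
        return float(np.hypot(deltas[:, 0], deltas[:, 1]).min())
    boundary = geo.hull.boundary
    target = boundary if not boundary.is_empty else geo.hull
    return float(geo.centre_point.distance(target))


def _m_angle(entity, grid, geo):
    pts = np.unique(geo.outline, axis=0)
    deltas = pts - np.array(geo.centre)
    nonzero = deltas[(deltas != 0).any(axis=1)]
    if len(pts) == 1:
        return 360.0 if len(nonzero) == 0 else 0.0
    if geo.hull.covers(geo.centre_point):
        return 360.0
    angles = np.sort(np.degrees(np.arctan2(nonzero[:, 0], nonzero[:, 1])))
    gaps = np.diff(np.append(angles, angles[0] + 360.0))
    return float(min(max(360.0 - gaps.max(), 0.0), 360.0))


def _m_centroid_x(entity, grid, geo):
    if isinstance(entity, DetectedRegion):
        return entity.centroid[1]
    centroid = geo.hull.centroid
    return float(centroid.x)


def _m_centroid_y(entity, grid, geo):
    if isinstance(entity, DetectedRegion):
        return entity.centroid[0]
    centroid = geo.hull.centroid
    return float(centroid.y)


def _m_clusteredness(entity, grid, geo):
    if isinstance(entity, DetectedRegion):
        filled = ndimage.binary_fill_holes(entity.mask)
        return float(entity.mask.sum() / filled.sum())
    pts = geo.positions.astype(float)
    if len(pts) < 2:
        return 1.0
    diff = pts[:, None, :] - pts[None, :, :]
    dists = np.hypot(diff[..., 0], diff[..., 1])
    mean_pairwise = dists[np.triu_indices(len(pts), k=1)].mean()
    diagonal = math.hypot(grid.shape[0] - 1, grid.shape[1] - 1)
    return float(1.0 - mean_pairwise / diagonal) if diagonal > 0 else 1.0


def _m_rectangle(entity, grid, geo):
    if geo.hull_area == 0:
        return 1.0
    envelope = shapely.oriented_envelope(geo.hull)
    return float(geo.hull_area / envelope.area)


def _m_circle(entity, grid, geo):
    if geo.hull_area == 0:
        return 1.0
    radius = shapely.minimum_bounding_radius(geo.hull)
    return float(geo.hull_area / (math.pi * radius ** 2))


def _m_triangle(entity, grid, geo):
    if geo.hull_area == 0:
        return 1.0
    hull_pts = np.asarray(geo.hull.exterior.coords)[:-1]
    return float(geo.hull_area / _min_enclosing_triangle_area(hull_pts))


def _min_enclosing_triangle_area(points: np.ndarray) -> float:
    """Smallest enclosing-triangle area found over a direction search.

    Candidate triangles are intersections of three supporting half-planes
    of the convex hull; directions are the hull edge normals plus a
    uniform fan.  Every candidate encloses the hull, so the result upper
    bounds the true minimum (shape measures stay within [0, 1]).
    """
    edges = np.diff(np.vstack([points, points[:1]]), axis=0)
    edge_angles = np.arctan2(edges[:, 1], edges[:, 0]) + np.pi / 2
    fan = np.linspace(0.0, 2 * np.pi, 36, endpoint=False)
    angles = np.unique(np.round(np.concatenate([edge_angles, fan]), 9) % (2 * np.pi))
    normals = np.column_stack([np.cos(angles), np.sin(angles)])
    support = (normals @ points.T).max(axis=1)

    triples = np.array(list(itertools.combinations(range(len(angles)), 3)))
    n1, n2, n3 = (normals[triples[:, k]] for k in range(3))
    h1, h2, h3 = (support[triples[:, k]] for k in range(3))

    def intersect(na, ha, nb, hb):
        det = na[:, 0] * nb[:, 1] - na[:, 1] * nb[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            x = (ha * nb[:, 1] - hb * na[:, 1]) / det
            y = (na[:, 0] * hb - nb[:, 0] * ha) / det
        return np.column_stack([x, y]), det

    v12, d12 = intersect(n1, h1, n2, h2)
    v23, d23 = intersect(n2, h2, n3, h3)
    v13, d13 = intersect(n1, h1, n3, h3)
    tol = 1e-9
    # Bounded intersection requires the three outward normals to span the
    # plane positively: all cyclic gaps between their angles below pi.
    a1, a2, a3 = (angles[triples[:, k]] for k in range(3))  # sorted: a1<a2<a3
    spanning = ((a2 - a1 < np.pi - tol) & (a3 - a2 < np.pi - tol)
                & (2 * np.pi - (a3 - a1) < np.pi - tol))
    valid = spanning
    valid &= (np.abs(d12) > tol) & (np.abs(d23) > tol) & (np.abs(d13) > tol)
    valid &= (v12 * n3).sum(axis=1) <= h3 + tol
    valid &= (v23 * n1).sum(axis=1) <= h1 + tol
    valid &= (v13 * n2).sum(axis=1) <= h2 + tol
    a = v23 - v12
    b = v13 - v12
    areas = 0.5 * np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
    areas = np.where(valid & np.isfinite(areas), areas, np.inf)
    best = areas.min()
    if not np.isfinite(best):  # pathological fallback: axis-aligned box * 2
        spans = points.max(axis=0) - points.min(axis=0)
        return float(2.0 * spans[0] * spans[1]) or 1.0
    return float(best)


_BUILTIN_MEASURES = {
    "clusteredness": _m_clusteredness,
    "density": _m_density,
    "area": _m_area,
    "perimeter": _m_perimeter,
    "distanceFromOrigin": _m_distance_from_origin,
    "angle": _m_angle,
    "triangleMeasure": _m_triangle,
    "rectangleMeasure": _m_rectangle,
    "circleMeasure": _m_circle,
    "centroidX": _m_centroid_x,
    "centroidY": _m_centroid_y,
}


# ---------------------------------------------------------------------------
# Snapshot-level orchestration
# ---------------------------------------------------------------------------

def analyse_snapshot(grid: GridSnapshot, rp: RegionParams, cp: ClusterParams,
                     registry: SpatialRegistry) -> list[SpatialEntityRecord]:
    """Detect all entities in one snapshot and annotate them with measures.

    Output order: regions (by seed position), then clusters (by earliest
    member region index); both annotated with the snapshot's vertex.
    """
    records = []
    regions = detect_regions(grid, rp)
    clusters = detect_clusters(regions, cp) if "clusters" in registry.entity_types \
        else []
    if "regions" in registry.entity_types:
        for region in regions:
            region.measures = compute_measures(region, grid, registry)
            records.append(SpatialEntityRecord.create(
                "regions", grid.scale_subsystem, region.measures))
    for cluster in clusters:
        cluster.measures = compute_measures(cluster, grid, registry)
        records.append(SpatialEntityRecord.create(
            "clusters", grid.scale_subsystem, cluster.measures))
    return records
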