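"""Order and cohesion measurements on point configurations.

All functions here are pure functions of the point set: Voronoi
tessellation clipped to a region, topological (Voronoi-edge-sharing)
adjacency, the sixfold positional-orientational order parameter Psi6, the
translational order parameter T, Voronoi polygon areas ("domains of
danger") and cluster decomposition.

Two clipping conventions are provided.  ``clip='box'`` intersects cells
with the simulation box; ``clip='hull'`` intersects them with the convex
hull of the point set inflated by ``hull_pad`` — the occupied-region
convention, which keeps rim agents' areas from being dominated by empty
space when a compact swarm sits in a much larger box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import QhullError, Voronoi, cKDTree
from shapely.geometry import LineString, MultiPoint, Polygon, box as shapely_box

__all__ = [
    "DegenerateGeometryError",
    "TopologicalGraph",
    "MetricsRecord",
    "bounded_voronoi_cells",
    "voronoi_topological_graph",
    "psi6_per_agent",
    "psi6_global",
    "translational_T",
    "voronoi_areas",
    "area_reduction",
    "cluster_components",
    "evaluate_state",
]

_EDGE_EPS = 1e-12  # minimum shared-edge length to count as adjacency
_BOUNDARY_TOL = 1e-9  # cell-touches-clip-boundary tolerance


class DegenerateGeometryError(ValueError):
    """Raised when a tessellation is undefined (n < 3, collinear points...)."""


@dataclass(frozen=True)
class TopologicalGraph:
    """Voronoi adjacency: pairs whose clipped polygons share an edge."""

    n: int
    adjacency: FrozenSet[Tuple[int, int]]

    def neighbours(self, i: int) -> List[int]:
        out = [b if a == i else a for a, b in self.adjacency if i in (a, b)]
        return sorted(out)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for a, b in self.adjacency:
            deg[a] += 1
            deg[b] += 1
        return deg


@dataclass(frozen=True)
class MetricsRecord:
    """Summary metrics of one configuration."""

    t: int
    psi6: float
    T: float
    mean_area: float
    total_area: float
    n_clusters: int


def _as_points(positions) -> np.ndarray:
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("positions must have shape (n, 2)")
    return pts


def _check_tessellable(pts: np.ndarray) -> None:
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 points for a tessellation")
    centred = pts - pts.mean(axis=0)
    scale = np.abs(centred).max()
    if scale == 0.0 or np.linalg.svd(centred, compute_uv=False)[-1] < 1e-12 * scale:
        raise DegenerateGeometryError("points are collinear or coincident")


def _clip_region(pts: np.ndarray, box: float | Polygon, clip: str, hull_pad: float) -> Polygon:
    if isinstance(box, Polygon):
        region = box
    else:
        region = shapely_box(0.0, 0.0, float(box), float(box))
    if clip == "box":
        return region
    if clip == "hull":
        hull = MultiPoint(pts).convex_hull
        if hull.area <= 0.0:
            raise DegenerateGeometryError("convex hull of points is degenerate")
        return hull.buffer(hull_pad) if hull_pad > 0 else hull
    raise ValueError("clip must be 'box' or 'hull'")


def _mirrored_voronoi(pts: np.ndarray, bounds: Tuple[float, float, float, float]) -> Voronoi:
    """Voronoi of the points plus their reflections across the four sides
    of ``bounds`` (slightly padded so that points lying exactly on the
    boundary do not coincide with their mirror image); the first-n cells
    are then all finite and cover ``bounds``."""
    minx, miny, maxx, maxy = bounds
    pad = 1e-6 * max(maxx - minx, maxy - miny)
    minx -= pad
    miny -= pad
    maxx += pad
    maxy += pad
    left = np.column_stack([2 * minx - pts[:, 0], pts[:, 1]])
    right = np.column_stack([2 * maxx - pts[:, 0], pts[:, 1]])
    down = np.column_stack([pts[:, 0], 2 * miny - pts[:, 1]])
    up = np.column_stack([pts[:, 0], 2 * maxy - pts[:, 1]])
    try:
        return Voronoi(np.vstack([pts, left, right, down, up]))
    except QhullError as exc:
        raise DegenerateGeometryError(f"Voronoi tessellation failed: {exc}") from None


def bounded_voronoi_cells(
    positions, box: float | Polygon, clip: str = "box", hull_pad: float = 0.0
) -> List[Polygon]:
    """Voronoi cell polygon of each point, clipped to the chosen region.

    The cells partition the region: their areas sum to its area.
    """
    pts = _as_points(positions)
    n = len(pts)
    _check_tessellable(pts)
    region = _clip_region(pts, box, clip, hull_pad)
    vor = _mirrored_voronoi(pts, region.bounds)
    cells = []
    for k in range(n):
        idx = vor.regions[vor.point_region[k]]
        if -1 in idx:  # pragma: no cover - cannot happen with mirroring
            raise DegenerateGeometryError("unbounded cell after mirroring")
        poly = Polygon(vor.vertices[idx]).intersection(region)
        cells.append(poly)
    return cells


def voronoi_topological_graph(
    positions, box: float | Polygon, clip: str = "box", hull_pad: float = 0.0
) -> TopologicalGraph:
    """Adjacency of pairs whose Voronoi polygons share an edge of positive
    length inside the clip region (metric-free, topological neighbours)."""
    pts = _as_points(positions)
    n = len(pts)
    _check_tessellable(pts)
    region = _clip_region(pts, box, clip, hull_pad)
    vor = _mirrored_voronoi(pts, region.bounds)
    edges = set()
    for (a, b), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if a >= n or b >= n:
            continue
        if -1 in rv:  # pragma: no cover
            continue
        seg = LineString(vor.vertices[rv]).intersection(region)
        if seg.length > _EDGE_EPS:
            edges.add((min(a, b), max(a, b)))
    return TopologicalGraph(n=n, adjacency=frozenset(edges))


def psi6_per_agent(positions, graph: TopologicalGraph) -> np.ndarray:
    """Complex psi6(i) = mean over topological neighbours j of exp(6i*theta_ij),
    theta_ij the bond angle to the positive x-axis."""
    pts = _as_points(positions)
    psi = np.zeros(len(pts), dtype=complex)
    neigh: Dict[int, List[int]] = {i: [] for i in range(len(pts))}
    for a, b in graph.adjacency:
        neigh[a].append(b)
        neigh[b].append(a)
    for i, js in neigh.items():
        if not js:
            raise DegenerateGeometryError(f"agent {i} has no topological neighbours")
        d = pts[js] - pts[i]
        theta = np.arctan2(d[:, 1], d[:, 0])
        psi[i] = np.exp(6j * theta).mean()
    return psi


def _interior_mask(cells: Sequence[Polygon], region: Polygon) -> np.ndarray:
    boundary = region.boundary
    return np.array([cell.distance(boundary) > _BOUNDARY_TOL for cell in cells])


def psi6_global(
    positions,
    box: float | Polygon,
    interior_only: bool = False,
    clip: str = "box",
    hull_pad: float = 0.0,
) -> float:
    """Norm of the agent-averaged psi6(i): 1 on a perfect triangular
    lattice, near 0 for disordered points.  Invariant under global
    translation and rotation of the point set (exactly so with
    ``clip='hull'``, whose clip region moves with the points; with
    ``clip='box'`` the adjacency of rim pairs whose shared ridge runs far
    from the swarm can depend on where the walls cut it).

    With ``interior_only`` the average excludes rim agents whose clipped
    cell touches the clip-region boundary (their bond counts are distorted
    by the clipping); each retained agent's own bonds still include rim
    neighbours.
    """
    pts = _as_points(positions)
    graph = voronoi_topological_graph(pts, box, clip=clip, hull_pad=hull_pad)
    psi = psi6_per_agent(pts, graph)
    if interior_only:
        region = _clip_region(pts, box, clip, hull_pad)
        cells = bounded_voronoi_cells(pts, box, clip=clip, hull_pad=hull_pad)
        mask = _interior_mask(cells, region)
        if not mask.any():
            raise DegenerateGeometryError("no interior agents under this clipping")
        psi = psi[mask]
    return float(abs(psi.mean()))


def translational_T(positions, r_T: float, include_self: bool = True) -> float:
    """Mean number of individuals within distance ``r_T`` of each
    individual (the focal one included by default).

    On the triangular lattice with spacing D and D < r_T < sqrt(3)*D this
    counts self + the 6 first-shell neighbours = 7; for isolated pairs it
    gives 2; hence it separates crystal from fragmented arrangements.
    """
    pts = _as_points(positions)
    if r_T <= 0:
        raise ValueError("r_T must be positive")
    counts = cKDTree(pts).query_ball_point(pts, r=r_T, return_length=True)
    mean = float(np.mean(counts))
    return mean if include_self else mean - 1.0


def voronoi_areas(
    positions, box: float | Polygon, clip: str = "box", hull_pad: float = 0.0
) -> np.ndarray:
    """Area of each agent's clipped Voronoi polygon (its domain of danger).
    Areas are non-negative and sum to the clip-region area."""
    cells = bounded_voronoi_cells(positions, box, clip=clip, hull_pad=hull_pad)
    return np.array([cell.area for cell in cells])


def area_reduction(
    initial,
    final,
    box: float | Polygon,
    clip: str = "hull",
    hull_pad: float = 0.0,
) -> float:
    """Fractional reduction of the mean domain-of-danger area between two
    configurations: ``1 - mean_area(final) / mean_area(initial)``.

    Positive values mean compaction.  The default occupied-region (hull)
    convention measures the area the swarm actually covers, so compaction
    of a swarm inside a much larger box registers fully.
    """
    a0 = voronoi_areas(initial, box, clip=clip, hull_pad=hull_pad).mean()
    a1 = voronoi_areas(final, box, clip=clip, hull_pad=hull_pad).mean()
    return float(1.0 - a1 / a0)


def cluster_components(positions, link_dist: float) -> np.ndarray:
    """Connected components of the graph linking pairs closer than
    ``link_dist``; returns one integer label per agent."""
    pts = _as_points(positions)
    if link_dist <= 0:
        raise ValueError("link_dist must be positive")
    n = len(pts)
    pairs = cKDTree(pts).query_pairs(r=link_dist, output_type="ndarray")
    if len(pairs) == 0:
        return np.arange(n)
    data = np.ones(len(pairs))
    adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def evaluate_state(
    positions,
    box: float,
    D: float,
    t: int = 0,
    rt_factor: float = 1.3,
    link_factor: float = 1.5,
    area_clip: str = "hull",
) -> MetricsRecord:
    """Standard metric bundle for one configuration: Psi6 (box-clipped,
    all agents), T at radius ``rt_factor * D``, mean/total occupied-region
    Voronoi area (hull inflated by D/2), and the number of clusters at
    linking distance ``link_factor * D``."""
    psi6 = psi6_global(positions, box)
    T = translational_T(positions, rt_factor * D)
    areas = voronoi_areas(positions, box, clip=area_clip,
                          hull_pad=D / 2 if area_clip == "hull" else 0.0)
    labels = cluster_components(positions, link_factor * D)
    return MetricsRecord(
        t=t,
        psi6=psi6,
        T=T,
        mean_area=float(areas.mean()),
        total_area=float(areas.sum()),
        n_clusters=int(labels.max()) + 1,
    )
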