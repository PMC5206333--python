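"""Monmonier maximum-difference barrier detection.

Populations are connected by a Delaunay triangulation of their (locally
projected) coordinates; a barrier starts at the uncrossed Delaunay edge with
the largest genetic distance and grows across the dual Voronoi diagram,
repeatedly crossing the adjacent uncrossed edge with the largest distance in
both directions until it reaches the network boundary or closes a loop.
Subsequent barriers repeat the procedure on the remaining edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .distances import EARTH_RADIUS_M, DistanceMatrix

__all__ = ["DelaunayNetwork", "Barrier", "BarrierSet", "delaunay_network", "monmonier_barriers"]


def _project(coords: dict[str, tuple[float, float]], labels: list[str]) -> np.ndarray:
    """Equirectangular projection (metres) centred on the population centroid."""
    lat = np.radians([coords[l][0] for l in labels])
    lon = np.radians([coords[l][1] for l in labels])
    lat0 = lat.mean()
    x = EARTH_RADIUS_M * np.cos(lat0) * (lon - lon.mean())
    y = EARTH_RADIUS_M * (lat - lat0)
    return np.column_stack([x, y])


@dataclass
class DelaunayNetwork:
    labels: list[str]
    points: np.ndarray  # projected xy
    edges: list[tuple[int, int]]  # vertex index pairs, i < j
    edge_triangles: dict[tuple[int, int], list[int]]  # edge -> adjacent simplex ids
    triangles: np.ndarray  # simplices (n_tri x 3)

    def edge_labels(self, edge: tuple[int, int]) -> tuple[str, str]:
        return (self.labels[edge[0]], self.labels[edge[1]])

    def is_boundary(self, edge: tuple[int, int]) -> bool:
        return len(self.edge_triangles[edge]) == 1


def delaunay_network(
    coords: dict[str, tuple[float, float]],
    labels: list[str] | None = None,
    jitter_seed: int = 0,
) -> DelaunayNetwork:
    """Delaunay triangulation of population sites with Voronoi-dual adjacency.

    Collinear/degenerate configurations fall back to a tiny seeded jitter
    (1 m scale) so a triangulation always exists for >= 3 sites.
    """
    labels = list(labels) if labels is not None else list(coords)
    if len(labels) < 3:
        raise ValueError("need at least three populations")
    pts = _project(coords, labels)
    try:
        tri = Delaunay(pts)
        if tri.simplices.size == 0:
            raise ValueError("degenerate triangulation")
    except Exception:
        rng = np.random.default_rng(jitter_seed)
        tri = Delaunay(pts + rng.normal(scale=1.0, size=pts.shape))
    edge_triangles: dict[tuple[int, int], list[int]] = {}
    for t, simplex in enumerate(tri.simplices):
        for a, b in ((0, 1), (1, 2), (0, 2)):
            e = tuple(sorted((int(simplex[a]), int(simplex[b]))))
            edge_triangles.setdefault(e, []).append(t)
    edges = sorted(edge_triangles)
    return DelaunayNetwork(labels, pts, edges, edge_triangles, tri.simplices)


@dataclass
class Barrier:
    crossed: list[tuple[str, str]]  # population pairs, in crossing order
    distances: list[float]
    reached_boundary: bool
    closed_loop: bool


@dataclass
class BarrierSet:
    barriers: list[Barrier]
    network: DelaunayNetwork
    notice: str | None = None

    def orders(self) -> dict[str, Barrier]:
        """Barriers keyed by order letter, 'a' = first/strongest."""
        return {chr(ord("a") + i): b for i, b in enumerate(self.barriers)}

    def separated(self, pop_a: str, pop_b: str, upto: int | None = None) -> bool:
        """True when removing the crossed edges of barriers 1..upto disconnects
        the two populations in the Delaunay graph."""
        upto = len(self.barriers) if upto is None else upto
        removed = {
            tuple(sorted(e)) for b in self.barriers[:upto] for e in b.crossed
        }
        adj: dict[str, set[str]] = {l: set() for l in self.network.labels}
        for e in self.network.edges:
            la, lb = self.network.edge_labels(e)
            if tuple(sorted((la, lb))) not in removed:
                adj[la].add(lb)
                adj[lb].add(la)
        seen = {pop_a}
        stack = [pop_a]
        while stack:
            cur = stack.pop()
            if cur == pop_b:
                return False
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return True


def _edge_key(net: DelaunayNetwork, edge: tuple[int, int]) -> tuple[str, str]:
    return tuple(sorted(net.edge_labels(edge)))


def barrier_polylines(bset: BarrierSet) -> dict:
    """GeoJSON-style polylines of the Voronoi segments each barrier follows.

    Each crossed Delaunay edge contributes the segment between the
    circumcentres of its adjacent triangles (projected metres); hull edges
    contribute a short outward stub from their single circumcentre toward
    the edge midpoint.
    """
    net = bset.network

    def circumcentre(tri_idx: int) -> np.ndarray:
        a, b, c = net.points[net.triangles[tri_idx]]
        d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
        uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
        return np.array([ux, uy])

    label_idx = {l: i for i, l in enumerate(net.labels)}
    features = []
    for order, barrier in enumerate(bset.barriers):
        segments = []
        for la, lb in barrier.crossed:
            e = tuple(sorted((label_idx[la], label_idx[lb])))
            tris = net.edge_triangles[e]
            if len(tris) == 2:
                p1, p2 = circumcentre(tris[0]), circumcentre(tris[1])
            else:
                p1 = circumcentre(tris[0])
                mid = net.points[list(e)].mean(axis=0)
                p2 = mid + (mid - p1)
            segments.append([[float(p1[0]), float(p1[1])], [float(p2[0]), float(p2[1])]])
        features.append({
            "type": "Feature",
            "properties": {"order": chr(ord("a") + order)},
            "geometry": {"type": "MultiLineString", "coordinates": segments},
        })
    return {"type": "FeatureCollection", "features": features}


def monmonier_barriers(
    network: DelaunayNetwork,
    d: DistanceMatrix,
    max_barriers: int = 9,
) -> BarrierSet:
    """Trace up to ``max_barriers`` Monmonier barriers on the network.

    Ties in edge distance are broken by lexicographic population-pair order
    (deterministic). Crossed edges are removed from candidacy for later
    barriers. Fewer barriers are returned (with a notice) when the network
    runs out of uncrossed edges.
    """
    if max_barriers < 1:
        raise ValueError("max_barriers must be >= 1")
    lab_index = {l: i for i, l in enumerate(d.labels)}
    missing = [l for l in network.labels if l not in lab_index]
    if missing:
        raise ValueError(f"distance matrix lacks populations: {missing}")

    def dist(edge: tuple[int, int]) -> float:
        a, b = network.edge_labels(edge)
        return float(d.values[lab_index[a], lab_index[b]])

    crossed: set[tuple[int, int]] = set()
    barriers: list[Barrier] = []
    notice = None
    for _ in range(max_barriers):
        candidates = [e for e in network.edges if e not in crossed]
        if not candidates:
            notice = f"network exhausted after {len(barriers)} barriers"
            break
        start = max(candidates, key=lambda e: (dist(e), _edge_key(network, e)))
        # grow across the Voronoi diagram from both sides of the start edge
        path = [start]
        dists = [dist(start)]
        crossed.add(start)
        boundary = network.is_boundary(start)
        loop = False
        visited_tris: set[int] = set()
        for tri0 in network.edge_triangles[start]:
            tri = tri0
            while True:
                if tri in visited_tris:
                    loop = True
                    break
                visited_tris.add(tri)
                simplex = network.triangles[tri]
                opts = []
                for a, b in ((0, 1), (1, 2), (0, 2)):
                    e = tuple(sorted((int(simplex[a]), int(simplex[b]))))
                    if e not in crossed:
                        opts.append(e)
                if not opts:
                    break
                nxt = max(opts, key=lambda e: (dist(e), _edge_key(network, e)))
                crossed.add(nxt)
                path.append(nxt)
                dists.append(dist(nxt))
                adj = [t for t in network.edge_triangles[nxt] if t != tri]
                if not adj:  # hull edge: boundary reached
                    boundary = True
                    break
                tri = adj[0]
        barriers.append(
            Barrier(
                crossed=[network.edge_labels(e) for e in path],
                distances=dists,
                reached_boundary=boundary,
                closed_loop=loop,
            )
        )
    return BarrierSet(barriers, network, notice)
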