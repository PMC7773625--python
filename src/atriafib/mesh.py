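"""Surface-mesh data model and basic geometry.

The package works on open triangulated surfaces of the left or right atrium.
Everything downstream (coordinates, fibre mapping, simulation) sits on top of
:class:`SurfaceMesh`, per-element :class:`FibreField` vectors, and the point
cloud of fibre samples (:class:`VectorSampleCloud`) that emulates the primary
eigenvector output of DT-MRI.

Units are millimetres throughout. Vertex/triangle indexing is 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceMesh",
    "FibreField",
    "VectorSampleCloud",
    "MeshTopologyError",
    "detect_rims",
    "geodesic_path",
    "barycentric_locate",
]


class MeshTopologyError(ValueError):
    """Raised for meshes violating the open-manifold assumptions."""


@dataclass
class SurfaceMesh:
    """Oriented open triangulated surface with labelled rim boundary loops.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex positions in mm.
    triangles : (M, 3) int array
        0-based vertex index triples with consistent orientation
        (normals away from the chamber blood-pool centroid).
    rim_labels : dict
        Maps a rim name (``MV``, ``LSPV``, ... ``TV``, ``SVC``, ...) to an
        ordered closed boundary vertex loop.
    landmarks : dict
        Named single-vertex anatomical landmarks (e.g. ``LAA_tip``).
    chamber : {"LA", "RA", None}
    layer : {"endo", "epi", None}
    """

    vertices: np.ndarray
    triangles: np.ndarray
    rim_labels: dict[str, np.ndarray] = field(default_factory=dict)
    landmarks: dict[str, int] = field(default_factory=dict)
    chamber: str | None = None
    layer: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (M, 3)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise MeshTopologyError("triangle index out of range")
        self._cache: dict[str, object] = {}

    # -- basic sizes ---------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    # -- derived geometry (cached) -------------------------------------
    def _cached(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    def triangle_normals(self) -> np.ndarray:
        """Unit normals per triangle (orientation as stored)."""

        def compute():
            p = self.vertices[self.triangles]
            n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            if np.any(norm < 1e-14):
                raise MeshTopologyError("zero-area triangle present")
            return n / norm

        return self._cached("normals", compute)

    def triangle_areas(self) -> np.ndarray:
        def compute():
            p = self.vertices[self.triangles]
            n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
            return 0.5 * np.linalg.norm(n, axis=1)

        return self._cached("areas", compute)

    def triangle_centroids(self) -> np.ndarray:
        return self._cached(
            "centroids", lambda: self.vertices[self.triangles].mean(axis=1)
        )

    def edges_with_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique undirected edges and the number of incident triangles."""

        def compute():
            e = np.concatenate(
                [
                    self.triangles[:, [0, 1]],
                    self.triangles[:, [1, 2]],
                    self.triangles[:, [2, 0]],
                ]
            )
            e = np.sort(e, axis=1)
            uniq, counts = np.unique(e, axis=0, return_counts=True)
            return uniq, counts

        return self._cached("edges", compute)

    def boundary_edges(self) -> np.ndarray:
        """Edges incident to exactly one triangle, as (K, 2) sorted pairs."""
        edges, counts = self.edges_with_counts()
        if np.any(counts > 2):
            raise MeshTopologyError("non-manifold edge (shared by >2 triangles)")
        return edges[counts == 1]

    def vertex_adjacency(self) -> csr_matrix:
        """Sparse symmetric adjacency weighted by Euclidean edge length."""

        def compute():
            edges, _ = self.edges_with_counts()
            w = np.linalg.norm(
                self.vertices[edges[:, 0]] - self.vertices[edges[:, 1]], axis=1
            )
            n = self.n_vertices
            rows = np.concatenate([edges[:, 0], edges[:, 1]])
            cols = np.concatenate([edges[:, 1], edges[:, 0]])
            data = np.concatenate([w, w])
            return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()

        return self._cached("adjacency", compute)

    def orient_outward(self) -> None:
        """Flip triangles so normals point away from the vertex centroid."""
        centre = self.vertices.mean(axis=0)
        n = self.triangle_normals()
        outward = np.einsum("ij,ij->i", n, self.triangle_centroids() - centre)
        flip = outward < 0
        if flip.any():
            self.triangles[flip] = self.triangles[flip][:, [0, 2, 1]]
            self._cache.clear()

    def validate(self) -> None:
        """Check manifoldness, orientation consistency and triangle quality."""
        edges, counts = self.edges_with_counts()
        if np.any(counts > 2):
            raise MeshTopologyError("non-manifold edge (shared by >2 triangles)")
        if np.any(self.triangle_areas() < 1e-12):
            raise MeshTopologyError("zero-area triangle present")
        # consistent orientation: every interior edge appears once per direction
        directed = np.concatenate(
            [
                self.triangles[:, [0, 1]],
                self.triangles[:, [1, 2]],
                self.triangles[:, [2, 0]],
            ]
        )
        _, d_counts = np.unique(directed, axis=0, return_counts=True)
        if np.any(d_counts > 1):
            raise MeshTopologyError("inconsistent triangle orientation")


@dataclass
class FibreField:
    """Per-element sense-free unit tangent vectors (myocyte orientation).

    ``v`` and ``-v`` are equivalent. Vectors lie in their triangle's plane.
    """

    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.ascontiguousarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError("fibre vectors must be (M, 3)")

    def __len__(self) -> int:
        return len(self.vectors)

    def validate(self, mesh: SurfaceMesh, atol: float = 1e-6) -> None:
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=atol):
            raise ValueError("fibre vectors must be unit length")
        dots = np.einsum("ij,ij->i", self.vectors, mesh.triangle_normals())
        if np.max(np.abs(dots)) > atol:
            raise ValueError("fibre vectors must be tangent to their triangle")


@dataclass
class VectorSampleCloud:
    """Point samples of unit fibre vectors (emulated DT-MRI eigenvectors)."""

    positions: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.vectors = np.ascontiguousarray(self.vectors, dtype=np.float64)
        if len(self.positions) == 0:
            raise ValueError("vector sample cloud must be nonempty")
        if self.positions.shape != self.vectors.shape or self.positions.shape[1] != 3:
            raise ValueError("positions and vectors must both be (K, 3)")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("cloud vectors must be unit length")

    def __len__(self) -> int:
        return len(self.positions)


# ----------------------------------------------------------------------
# rim detection
# ----------------------------------------------------------------------

def _boundary_loops(mesh: SurfaceMesh) -> list[np.ndarray]:
    """All closed boundary loops as ordered vertex cycles.

    Loops are traversed along the *directed* boundary edges, i.e. in the
    orientation induced by the (consistently oriented) triangles, so every
    rim of an outward-oriented mesh winds the same way.
    """
    edges, counts = mesh.edges_with_counts()
    if np.any(counts > 2):
        raise MeshTopologyError("non-manifold edge (shared by >2 triangles)")
    boundary = {tuple(e) for e in edges[counts == 1]}
    if not boundary:
        raise MeshTopologyError("mesh has no boundary (closed surface)")
    succ: dict[int, int] = {}
    for tri in mesh.triangles:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            if (min(a, b), max(a, b)) in boundary:
                a, b = int(a), int(b)
                if a in succ:
                    raise MeshTopologyError(
                        f"boundary vertex {a} has multiple outgoing boundary edges"
                    )
                succ[a] = b
    seen: set[int] = set()
    loops = []
    for start in sorted(succ):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = succ[start]
        while cur != start:
            loop.append(cur)
            seen.add(cur)
            cur = succ[cur]
        loops.append(np.asarray(loop, dtype=np.int64))
    # deterministic order: by smallest vertex id
    loops.sort(key=lambda lp: int(lp.min()))
    return loops


def detect_rims(
    mesh: SurfaceMesh, seed_points: dict[str, np.ndarray] | None = None
) -> dict[str, np.ndarray] | list[np.ndarray]:
    """Find boundary loops; optionally name them by nearest seed point.

    With ``seed_points`` (name -> 3D point) each name is assigned to the loop
    whose vertices come nearest that point. A seed equidistant to two loops is
    assigned to the loop of smaller index (a warning is logged). Without seeds
    the raw ordered loops are returned.
    """
    loops = _boundary_loops(mesh)
    if seed_points is None:
        return loops
    named: dict[str, np.ndarray] = {}
    for name, pt in seed_points.items():
        pt = np.asarray(pt, dtype=float)
        dists = np.array(
            [np.min(np.linalg.norm(mesh.vertices[lp] - pt, axis=1)) for lp in loops]
        )
        best = int(np.argmin(dists))
        ties = np.flatnonzero(np.isclose(dists, dists[best]))
        if len(ties) > 1:
            logger.warning(
                "rim seed %r equidistant to loops %s; keeping loop %d",
                name, ties.tolist(), best,
            )
        named[name] = loops[best]
    return named


# ----------------------------------------------------------------------
# geodesic (edge-graph shortest) paths
# ----------------------------------------------------------------------

def geodesic_path(
    mesh: SurfaceMesh,
    v_start: int,
    v_end: int,
    forbidden_vertices=None,
) -> np.ndarray:
    """Shortest path on the edge graph (Euclidean weights) between vertices.

    ``forbidden_vertices`` are removed from the graph; they may include
    neither endpoint. The path is returned as an ordered vertex id array
    (``[v_start]`` if the endpoints coincide).
    """
    v_start, v_end = int(v_start), int(v_end)
    if v_start == v_end:
        return np.asarray([v_start], dtype=np.int64)
    graph = mesh.vertex_adjacency()
    if forbidden_vertices is not None and len(np.atleast_1d(forbidden_vertices)):
        forbidden = np.unique(np.asarray(forbidden_vertices, dtype=np.int64))
        if v_start in forbidden or v_end in forbidden:
            raise ValueError("forbidden set must exclude both endpoints")
        mask = np.ones(mesh.n_vertices, dtype=bool)
        mask[forbidden] = False
        graph = graph.tolil()
        graph[~mask, :] = 0
        graph[:, ~mask] = 0
        graph = graph.tocsr()
        graph.eliminate_zeros()
    dist, pred = dijkstra(
        graph, directed=False, indices=v_start, return_predecessors=True
    )
    if not np.isfinite(dist[v_end]):
        raise MeshTopologyError(
            f"no path from {v_start} to {v_end} (disconnected after exclusion)"
        )
    path = [v_end]
    while path[-1] != v_start:
        path.append(int(pred[path[-1]]))
    return np.asarray(path[::-1], dtype=np.int64)


def path_length(mesh: SurfaceMesh, path: np.ndarray) -> float:
    p = mesh.vertices[np.asarray(path)]
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def mesh_components(mesh: SurfaceMesh) -> np.ndarray:
    """Connected-component label per vertex."""
    n, labels = connected_components(mesh.vertex_adjacency(), directed=False)
    return labels


# ----------------------------------------------------------------------
# 2D barycentric point location
# ----------------------------------------------------------------------

def _bary_weights_2d(points: np.ndarray, tri_xy: np.ndarray) -> np.ndarray:
    """Barycentric weights of ``points`` (Q,2) w.r.t. triangles (Q,3,2)."""
    a, b, c = tri_xy[:, 0], tri_xy[:, 1], tri_xy[:, 2]
    v0 = b - a
    v1 = c - a
    v2 = points - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-300, 1e-300, denom)
    w1 = (d11 * d20 - d01 * d21) / denom
    w2 = (d00 * d21 - d01 * d20) / denom
    w0 = 1.0 - w1 - w2
    return np.stack([w0, w1, w2], axis=1)


def barycentric_locate(
    points_2d: np.ndarray,
    vertices_2d: np.ndarray,
    triangles: np.ndarray,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Locate 2D points in a given triangulation.

    Returns ``(tri_ids, weights, n_snapped)``. Points inside (or within
    ``tol``) a triangle get that triangle's clamped-free weights; points
    outside every candidate snap to the nearest triangle with weights clamped
    to [0, 1] and renormalised. The snapped count is logged and returned.

    The search checks the triangles whose centroids are nearest the query
    (k-d tree), widening once before snapping; this is robust to the slightly
    distorted triangulations that arise in coordinate space.
    """
    points_2d = np.asarray(points_2d, dtype=float)
    vertices_2d = np.asarray(vertices_2d, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    q = len(points_2d)
    tri_xy = vertices_2d[triangles]  # (M,3,2)
    centroids = tri_xy.mean(axis=1)
    tree = cKDTree(centroids)
    tri_ids = np.full(q, -1, dtype=np.int64)
    weights = np.zeros((q, 3), dtype=float)
    pending = np.arange(q)
    for k in (8, 64):
        if len(pending) == 0:
            break
        kk = min(k, len(centroids))
        _, cand = tree.query(points_2d[pending], k=kk)
        cand = np.atleast_2d(cand)
        still = []
        for row, pi in enumerate(pending):
            cands = cand[row]
            w = _bary_weights_2d(
                np.repeat(points_2d[pi][None, :], len(cands), axis=0), tri_xy[cands]
            )
            inside = np.min(w, axis=1) >= -tol
            hit = np.flatnonzero(inside)
            if len(hit):
                j = int(hit[0])
                tri_ids[pi] = cands[j]
                weights[pi] = w[j]
            else:
                still.append(pi)
        pending = np.asarray(still, dtype=np.int64)
    n_snapped = len(pending)
    if n_snapped:
        _, nearest = tree.query(points_2d[pending], k=1)
        nearest = np.atleast_1d(nearest)
        w = _bary_weights_2d(points_2d[pending], tri_xy[nearest])
        w = np.clip(w, 0.0, 1.0)
        w /= w.sum(axis=1, keepdims=True)
        tri_ids[pending] = nearest
        weights[pending] = w
        logger.info("barycentric_locate: snapped %d/%d points", n_snapped, q)
    return tri_ids, weights, n_snapped
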