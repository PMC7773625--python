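"""Universal atrial coordinates (UAC).

Each atrium is mapped to the unit square by two discrete-harmonic coordinate
fields solved with cotangent-weight P1 finite elements and landmark-fixed
Dirichlet boundary conditions:

* **LA** — ``alpha`` runs septal (0) to lateral (1); ``beta`` runs from the
  posterior mitral-valve rim (0), over the roof (0.5), to the anterior
  mitral-valve rim (1). ``beta`` is solved on posterior/anterior sub-meshes
  split along a roof separating line and combined.
* **RA** — ``alpha`` runs lateral tricuspid valve (0) to septal tricuspid
  valve (1); ``beta`` runs inferior vena cava (0) to superior vena cava (1).

Anatomical structures (PVs, appendage tips, venae cavae, CS) are pinned to
configurable atlas coordinates so that the same structure lands at the same
place in every anatomy, which is what makes cross-anatomy registration of
fibre fields meaningful. Interior structure rims are pinned to small circles
around the atlas centre; the circle phase is matched to a provisional
(pin-free) solve, which keeps the flattening locally orientation-preserving.

The exact landmark/path recipe used here is recorded in
:data:`LA_ATLAS_DEFAULTS` / :data:`RA_ATLAS_DEFAULTS` and in the functions
below; it makes no claim of bit-compatibility with any externally deposited
coordinate fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .mesh import MeshTopologyError, SurfaceMesh, geodesic_path

logger = logging.getLogger(__name__)

__all__ = [
    "UACField",
    "BoundaryConditionSet",
    "cotangent_laplacian",
    "solve_laplace",
    "build_la_bcs",
    "build_ra_bcs",
    "compute_uac",
    "LA_ATLAS_DEFAULTS",
    "RA_ATLAS_DEFAULTS",
]

#: Atlas-fixed (alpha, beta) centres and pin radii for LA structures.
#: Septal structures (right PVs) sit at low alpha, lateral (left PVs) at
#: high alpha; inferior PVs at low beta, superior PVs near the roof.
#: ``radius: None`` means adaptive: the pin circle keeps the structure's
#: provisional (pin-free) size, which minimises fold-inducing distortion.
LA_ATLAS_DEFAULTS = {
    "RSPV": {"centre": (0.25, 0.44), "radius": None},
    "RIPV": {"centre": (0.19, 0.33), "radius": None},
    "LSPV": {"centre": (0.73, 0.44), "radius": None},
    "LIPV": {"centre": (0.79, 0.33), "radius": None},
    "LAA_tip": {"centre": (0.65, 0.63), "radius": 0.0},
}

#: Atlas-fixed coordinates for RA structures. SVC/IVC rims carry the beta
#: boundary conditions (1 / 0) directly and sit on the alpha = 0.5 seam
#: meridian; CS and the appendage tip are pinned like the LA structures.
RA_ATLAS_DEFAULTS = {
    "SVC": {"beta": 1.0},
    "IVC": {"beta": 0.0},
    "CS": {"centre": (0.72, 0.17), "radius": None},
    "RAA_tip": {"centre": (0.34, 0.40), "radius": 0.0},
}


@dataclass
class UACField:
    """Per-vertex (alpha, beta) coordinates in the unit square."""

    alpha: np.ndarray
    beta: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha and beta must have the same shape")

    def uv(self) -> np.ndarray:
        """Stacked (N, 2) coordinate array."""
        return np.stack([self.alpha, self.beta], axis=1)

    def __len__(self) -> int:
        return len(self.alpha)


class BoundaryConditionSet:
    """Named Dirichlet node sets with prescribed values in [0, 1].

    Sets added first win: later additions silently skip nodes that already
    carry a value (used to give separating-path values priority over rim
    values at the shared junction vertices).
    """

    def __init__(self) -> None:
        self.names: dict[str, np.ndarray] = {}
        self._value: dict[int, float] = {}
        #: optional lateral/septal seam path(s) (RA): the coordinate is
        #: solved on the mesh cut along these paths, making it double-valued
        #: there; seam_side_values/_marker assign per-side Dirichlet values
        self.seam_path: list | np.ndarray | None = None
        self.seam_side_values: tuple | None = None
        self.seam_marker: np.ndarray | None = None

    def add(self, name: str, nodes, values) -> None:
        nodes = np.atleast_1d(np.asarray(nodes, dtype=np.int64))
        values = np.broadcast_to(np.asarray(values, dtype=float), nodes.shape)
        if np.any((values < 0) | (values > 1)):
            raise ValueError(f"bc {name!r}: values must lie in [0, 1]")
        kept = []
        for n, v in zip(nodes, values):
            if int(n) not in self._value:
                self._value[int(n)] = float(v)
                kept.append(int(n))
        self.names[name] = np.asarray(kept, dtype=np.int64)

    @property
    def nodes(self) -> np.ndarray:
        return np.asarray(sorted(self._value), dtype=np.int64)

    @property
    def values(self) -> np.ndarray:
        return np.asarray([self._value[n] for n in sorted(self._value)], dtype=float)

    def __len__(self) -> int:
        return len(self._value)

    def restricted(self, vertex_set: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nodes/values present in ``vertex_set``."""
        mask = np.isin(self.nodes, vertex_set)
        return self.nodes[mask], self.values[mask]


# ----------------------------------------------------------------------
# cotangent Laplacian and harmonic solves
# ----------------------------------------------------------------------

def cotangent_laplacian(mesh: SurfaceMesh, triangle_ids=None) -> coo_matrix:
    """Cotangent-weight stiffness matrix (positive semi-definite).

    Negative weights from obtuse triangles are kept; the discrete maximum
    principle is then only guaranteed on Delaunay-quality meshes.
    """
    tris = mesh.triangles if triangle_ids is None else mesh.triangles[triangle_ids]
    p = mesh.vertices[tris]  # (M,3,3)
    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    for k in range(3):
        i = tris[:, (k + 1) % 3]
        j = tris[:, (k + 2) % 3]
        a = p[:, (k + 1) % 3] - p[:, k]
        b = p[:, (k + 2) % 3] - p[:, k]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        cross = np.maximum(cross, 1e-300)
        cot = np.einsum("ij,ij->i", a, b) / cross
        w = 0.5 * cot
        rows += [i, j, i, j]
        cols += [j, i, i, j]
        vals += [-w, -w, w, w]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def solve_laplace(
    mesh: SurfaceMesh,
    bc: BoundaryConditionSet,
    triangle_ids=None,
    check_residual: bool = True,
) -> np.ndarray:
    """Discrete harmonic field matching ``bc`` exactly.

    ``triangle_ids`` restricts the solve to a sub-mesh; vertices outside it
    are returned as NaN. Connected components of the solve region without any
    Dirichlet node raise an error listing the components.
    """
    if len(bc) == 0:
        raise ValueError("boundary condition set is empty")
    L = cotangent_laplacian(mesh, triangle_ids)
    tris = mesh.triangles if triangle_ids is None else mesh.triangles[triangle_ids]
    region = np.unique(tris)
    d_nodes, d_values = bc.restricted(region)
    if len(d_nodes) == 0:
        raise ValueError("no boundary-condition nodes inside solve region")

    # connectivity check on the solve region
    adj = (L != 0).astype(np.int8)
    sub = adj[region][:, region]
    ncomp, labels = connected_components(sub, directed=False)
    has_bc = np.zeros(ncomp, dtype=bool)
    pos_of = {int(v): i for i, v in enumerate(region)}
    for n in d_nodes:
        has_bc[labels[pos_of[int(n)]]] = True
    if not has_bc.all():
        missing = np.flatnonzero(~has_bc).tolist()
        raise MeshTopologyError(
            f"solve region has components without boundary conditions: {missing}"
        )

    x = np.full(mesh.n_vertices, np.nan)
    x[d_nodes] = d_values
    free = region[~np.isin(region, d_nodes)]
    if len(free):
        A = L[free][:, free].tocsc()
        rhs = -L[free][:, d_nodes] @ d_values
        sol = spsolve(A, rhs)
        x[free] = sol
        if check_residual:
            r = np.linalg.norm(A @ sol - rhs)
            scale = max(np.linalg.norm(rhs), 1.0)
            if r / scale > 1e-10:
                logger.warning("laplace solve residual %.3e above 1e-10", r / scale)
    return x


# ----------------------------------------------------------------------
# landmark/path recipe helpers
# ----------------------------------------------------------------------

def _loop_arc_fraction(mesh, loop, start_index=0, reverse=False):
    """Cumulative arc-length fraction t in [0,1) along a closed loop."""
    order = np.roll(loop, -start_index)
    if reverse:
        order = np.concatenate([[order[0]], order[1:][::-1]])
    pts = mesh.vertices[order]
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    total = seg.sum()
    t = np.concatenate([[0.0], np.cumsum(seg[:-1])]) / total
    return order, t


def _split_loop(loop: np.ndarray, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Split a closed loop at positions i, j into the two open arcs.

    Both arcs include the junction vertices at their ends.
    """
    if i == j:
        raise ValueError("split points must differ")
    if i > j:
        i, j = j, i
    arc1 = loop[i : j + 1]
    arc2 = np.concatenate([loop[j:], loop[: i + 1]])
    return arc1, arc2


def _nearest_loop_vertex(mesh, loop, point):
    d = np.linalg.norm(mesh.vertices[loop] - np.asarray(point, float), axis=1)
    return int(loop[int(np.argmin(d))])


def _circle_pin(bc_a, bc_b, mesh, name, loop, centre, radius, provisional=None):
    """Pin a rim loop onto a small circle around its atlas centre.

    When a provisional (alpha, beta) field is given, each rim vertex keeps
    its provisional angle about the rim's provisional centroid, which avoids
    twisting the flattening around the pinned structure. ``radius=None``
    keeps the structure's provisional RMS radius (clamped to [0.02, 0.08]).
    """
    loop = np.asarray(loop, dtype=np.int64)
    if provisional is not None:
        a0, b0 = provisional
        u = a0[loop] - np.nanmean(a0[loop])
        v = b0[loop] - np.nanmean(b0[loop])
        # provisional hole images are slit-like: keep each vertex's natural
        # angle (so the angular density of the slit is preserved and the
        # neighbourhood is distorted as little as possible) but enforce a
        # monotone winding so the pinned circle cannot self-fold
        area2 = float(np.sum(u * np.roll(v, -1) - np.roll(u, -1) * v))
        direction = 1.0 if area2 >= 0 else -1.0
        prov = direction * np.arctan2(v, u)
        steps = np.mod(np.diff(prov) + np.pi, 2 * np.pi) - np.pi
        unwrapped = prov[0] + np.concatenate([[0.0], np.cumsum(steps)])
        mono = np.maximum.accumulate(unwrapped)
        total = mono[-1] - mono[0]
        if total < 1e-9:
            _, t = _loop_arc_fraction(mesh, loop)
            mono = 2 * np.pi * t
            total = 2 * np.pi
        ang = direction * (prov[0] + (mono - mono[0]) * 2 * np.pi / total)
        if radius is None:
            radius = float(np.clip(np.nanmean(np.hypot(u, v)), 0.02, 0.045))
    else:
        _, t = _loop_arc_fraction(mesh, loop)
        ang = 2 * np.pi * t
        if radius is None:
            radius = 0.035
    bc_a.add(name, loop, centre[0] + radius * np.cos(ang))
    bc_b.add(name, loop, centre[1] + radius * np.sin(ang))


def _cut_mesh_along_path(triangles: np.ndarray, n_vertices: int, path: np.ndarray):
    """Duplicate the vertices of a path and reattach one side's triangles.

    Splits each path vertex's triangle fan at the incident cut edges (and at
    the surface boundary for endpoint vertices) into two components; the
    triangles of one side are remapped to fresh duplicate vertex ids. Side
    membership is propagated along the path so the slit is coherent.
    Returns ``(new_triangles, dup_of)`` with ``dup_of`` mapping original to
    duplicate ids starting at ``n_vertices``.
    """
    path = [int(v) for v in path]
    cutset = {frozenset((path[k], path[k + 1])) for k in range(len(path) - 1)}
    v2t: dict[int, list[int]] = {}
    for ti, tri in enumerate(triangles):
        for v in tri:
            v2t.setdefault(int(v), []).append(ti)

    def fan_components(v):
        local = v2t[v]
        idx = {t: i for i, t in enumerate(local)}
        adj = [[] for _ in local]
        # two fan triangles are adjacent iff they share a non-cut edge at v
        edge_owner: dict[int, int] = {}
        for t in local:
            tri = triangles[t]
            for u in tri:
                u = int(u)
                if u == v or frozenset((v, u)) in cutset:
                    continue
                if u in edge_owner:
                    a, b = idx[edge_owner[u]], idx[t]
                    adj[a].append(b)
                    adj[b].append(a)
                else:
                    edge_owner[u] = t
        comp = [-1] * len(local)
        c = 0
        for i in range(len(local)):
            if comp[i] >= 0:
                continue
            stack = [i]
            comp[i] = c
            while stack:
                j = stack.pop()
                for k in adj[j]:
                    if comp[k] < 0:
                        comp[k] = c
                        stack.append(k)
            c += 1
        groups = [[] for _ in range(c)]
        for i, t in enumerate(local):
            groups[comp[i]].append(t)
        return groups

    # seed side B with one of the two triangles on the first cut edge
    first_edge_tris = [
        t for t in v2t[path[0]] if path[1] in triangles[t]
    ]
    if len(first_edge_tris) != 2:
        raise MeshTopologyError("cut path runs along a boundary edge")
    side_b: set[int] = {first_edge_tris[1]}
    per_vertex_b: dict[int, list[int]] = {}
    for v in path:
        groups = fan_components(v)
        if len(groups) < 2:
            raise MeshTopologyError(f"cut path vertex {v} does not split its fan")
        b_groups = [g for g in groups if any(t in side_b for t in g)]
        if len(b_groups) != 1:
            raise MeshTopologyError(f"ambiguous cut side at vertex {v}")
        per_vertex_b[v] = b_groups[0]
        side_b.update(b_groups[0])

    dup_of = {v: n_vertices + i for i, v in enumerate(path)}
    side_b_tris = sorted(side_b)
    new_tris = triangles.copy()
    for v, tris_b in per_vertex_b.items():
        for t in tris_b:
            new_tris[t][new_tris[t] == v] = dup_of[v]
    return new_tris, dup_of, side_b_tris


def solve_with_seam(
    mesh: SurfaceMesh,
    bc: BoundaryConditionSet,
    seams,
    side_values: tuple | None = None,
    side_marker=None,
) -> np.ndarray:
    """Harmonic solve on the mesh cut open along one or more seam paths.

    Seam vertices are duplicated so the two sides decouple (the coordinate
    becomes double-valued along the seam); the returned per-original-vertex
    field carries the average of the two copies at seam vertices.

    With ``side_values = (v_near, v_far)`` the two copies of every seam path
    carry those Dirichlet values: ``v_near`` on the side whose triangles lie
    nearer the 3D point ``side_marker``. This anchors a coordinate that
    winds around the chamber (the angular jump happens exactly at the seam).
    Ordinary Dirichlet values on duplicated nodes apply to both copies.
    """
    if isinstance(seams, np.ndarray):
        seams = [seams]
    tris = mesh.triangles
    n = mesh.n_vertices
    dup_of: dict[int, int] = {}
    seam_bc_nodes: list[int] = []
    seam_bc_vals: list[float] = []
    for seam in seams:
        new_tris, dups, side_b = _cut_mesh_along_path(tris, n, seam)
        if side_values is not None:
            cent_b = mesh.vertices[mesh.triangles[side_b]].mean(axis=(0, 1))
            touching = sorted(
                {ti for ti, tri in enumerate(mesh.triangles)
                 if any(int(v) in set(int(s) for s in seam) for v in tri)}
            )
            side_a = [t for t in touching if t not in set(side_b)]
            cent_a = mesh.vertices[mesh.triangles[side_a]].mean(axis=(0, 1))
            marker = np.asarray(side_marker, dtype=float)
            v_near, v_far = side_values
            if np.linalg.norm(cent_a - marker) <= np.linalg.norm(cent_b - marker):
                val_a, val_b = v_near, v_far
            else:
                val_a, val_b = v_far, v_near
            for v in seam:
                seam_bc_nodes.append(int(v))
                seam_bc_vals.append(val_a)
                seam_bc_nodes.append(dups[int(v)])
                seam_bc_vals.append(val_b)
        tris = new_tris
        dup_of.update(dups)
        n += len(dups)
    new_vertices = np.concatenate(
        [mesh.vertices, mesh.vertices[sorted(dup_of, key=dup_of.get)]]
    )
    cut_mesh = SurfaceMesh(new_vertices, tris)
    cut_bc = BoundaryConditionSet()
    if seam_bc_nodes:
        cut_bc.add("seam_sides", seam_bc_nodes, seam_bc_vals)
    nodes, values = bc.nodes, bc.values
    if len(nodes):
        extra_nodes = [dup_of[int(v)] for v in nodes if int(v) in dup_of]
        extra_vals = [values[i] for i, v in enumerate(nodes) if int(v) in dup_of]
        all_nodes = np.concatenate([nodes, extra_nodes]) if extra_nodes else nodes
        all_vals = np.concatenate([values, extra_vals]) if extra_vals else values
        cut_bc.add("all", all_nodes, all_vals)
    x = solve_laplace(cut_mesh, cut_bc)
    out = x[: mesh.n_vertices].copy()
    for v, d in dup_of.items():
        out[v] = 0.5 * (x[v] + x[d])
    return out


@dataclass
class LAPartition:
    """Posterior/anterior triangle split along the roof separating line."""

    posterior_triangles: np.ndarray
    anterior_triangles: np.ndarray
    cut_path: np.ndarray  # ordered vertex ids, P_sept ... P_lat


def _partition_by_cut(mesh: SurfaceMesh, cut: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split triangles into the two components separated by a vertex path."""
    cut_edges = {
        (min(a, b), max(a, b)) for a, b in zip(cut[:-1], cut[1:])
    }
    cut_set = set(int(v) for v in cut)
    # triangle adjacency graph, cutting adjacencies across cut-path edges
    edge_to_tris: dict[tuple[int, int], list[int]] = {}
    for ti, tri in enumerate(mesh.triangles):
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (int(min(a, b)), int(max(a, b)))
            edge_to_tris.setdefault(key, []).append(ti)
    rows, cols = [], []
    for key, tl in edge_to_tris.items():
        if len(tl) == 2 and key not in cut_edges:
            rows.append(tl[0])
            cols.append(tl[1])
    m = mesh.n_triangles
    g = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    ncomp, labels = connected_components(g, directed=False)
    if ncomp != 2:
        raise MeshTopologyError(
            f"separating line yields {ncomp} components (expected 2); "
            "the cut path may touch a rim or not reach the boundary"
        )
    side0 = np.flatnonzero(labels == 0)
    side1 = np.flatnonzero(labels == 1)
    return side0, side1


def _roof_cut(mesh, rims, p_sept, p_lat, forbidden):
    """Concatenated geodesic P_sept -> W_sept -> W_lat -> P_lat over the roof."""
    allowed = np.ones(mesh.n_vertices, dtype=bool)
    allowed[forbidden] = False
    allowed[[p_sept, p_lat]] = True

    def waypoint(rim_name):
        c = mesh.vertices[rims[rim_name]].mean(axis=0)
        ids = np.flatnonzero(allowed)
        d = np.linalg.norm(mesh.vertices[ids] - c, axis=1)
        return int(ids[int(np.argmin(d))])

    w_sept = waypoint("RSPV")
    w_lat = waypoint("LSPV")
    forb = np.flatnonzero(~allowed)

    def forb_except(*keep):
        f = set(int(v) for v in forb)
        for k in keep:
            f.discard(int(k))
        return np.asarray(sorted(f), dtype=np.int64)

    seg1 = geodesic_path(mesh, p_sept, w_sept, forb_except(p_sept, w_sept))
    seg2 = geodesic_path(mesh, w_sept, w_lat, forb_except(w_sept, w_lat))
    seg3 = geodesic_path(mesh, w_lat, p_lat, forb_except(w_lat, p_lat))
    cut = np.concatenate([seg1, seg2[1:], seg3[1:]])
    # drop accidental revisits (keeps the path simple)
    _, first = np.unique(cut, return_index=True)
    cut = cut[np.sort(first)]
    return cut, seg1, seg3


def build_la_bcs(
    mesh: SurfaceMesh,
    rims: dict[str, np.ndarray],
    seed_point,
    atlas: dict | None = None,
    laa_tip: int | None = None,
):
    """Boundary conditions and posterior/anterior partition for the LA.

    Parameters
    ----------
    rims : dict with keys MV, LSPV, LIPV, RSPV, RIPV (ordered loops).
    seed_point : 3D point marking the septal end of the mitral-valve rim
        (the single manual landmark the LA construction needs).
    atlas : optional override of :data:`LA_ATLAS_DEFAULTS`.
    laa_tip : optional vertex id of the appendage tip to pin.

    Returns
    -------
    (bc_alpha, bc_beta, partition)
    """
    atlas = {**LA_ATLAS_DEFAULTS, **(atlas or {})}
    for need in ("MV", "LSPV", "LIPV", "RSPV", "RIPV"):
        if need not in rims:
            raise KeyError(f"missing rim label {need!r}")
    mv = np.asarray(rims["MV"], dtype=np.int64)

    # junction points: septal from the seed, lateral at half arc length
    p_sept = _nearest_loop_vertex(mesh, mv, seed_point)
    i_sept = int(np.flatnonzero(mv == p_sept)[0])
    order, t = _loop_arc_fraction(mesh, mv, start_index=i_sept)
    p_lat = int(order[int(np.argmin(np.abs(t - 0.5)))])

    # posterior half of the MV rim = the half nearer the PV centroid
    i = int(np.flatnonzero(mv == p_sept)[0])
    j = int(np.flatnonzero(mv == p_lat)[0])
    arc1, arc2 = _split_loop(mv, i, j)
    pv_centroid = np.mean(
        [mesh.vertices[rims[k]].mean(axis=0) for k in ("LSPV", "LIPV", "RSPV", "RIPV")],
        axis=0,
    )
    d1 = np.linalg.norm(mesh.vertices[arc1].mean(axis=0) - pv_centroid)
    d2 = np.linalg.norm(mesh.vertices[arc2].mean(axis=0) - pv_centroid)
    mv_post, mv_ant = (arc1, arc2) if d1 < d2 else (arc2, arc1)

    # forbid the posterior cap that contains the PVs, so the separating line
    # passes anterior of the superior veins
    centre = mesh.vertices.mean(axis=0)
    pv_dir = pv_centroid - centre
    pv_dir /= np.linalg.norm(pv_dir)
    proj = (mesh.vertices - centre) @ pv_dir
    pv_rim_all = np.concatenate([rims[k] for k in ("LSPV", "LIPV", "RSPV", "RIPV")])
    edge = float(np.median(np.linalg.norm(
        mesh.vertices[mesh.triangles[:, 0]] - mesh.vertices[mesh.triangles[:, 1]], axis=1
    )))
    tau = float(proj[pv_rim_all].min()) - 3.0 * edge
    forbidden = np.flatnonzero(proj > tau)
    forbidden = np.union1d(forbidden, pv_rim_all)
    forbidden = np.union1d(forbidden, mv)

    cut, septal_seg, lateral_seg = _roof_cut(mesh, rims, p_sept, p_lat, forbidden)
    posterior, anterior = _partition_by_cut(mesh, cut)
    # identify which side holds the posterior MV half
    post_set = set(int(v) for v in mv_post) - {p_sept, p_lat}
    in_side0 = np.isin(mesh.triangles[posterior], list(post_set)).any()
    if not in_side0:
        posterior, anterior = anterior, posterior
    partition = LAPartition(posterior, anterior, cut)

    bc_beta = BoundaryConditionSet()
    bc_beta.add("roof_line", cut, 0.5)
    bc_beta.add("MV_posterior", mv_post, 0.0)
    bc_beta.add("MV_anterior", mv_ant, 1.0)

    bc_alpha = BoundaryConditionSet()
    bc_alpha.add("septal_path", septal_seg, 0.0)
    bc_alpha.add("lateral_path", lateral_seg, 1.0)

    # provisional pin-free solve to phase-match the structure pins
    a0 = _combined_solve(mesh, bc_alpha, bc_beta, partition, check=False)
    for name in ("LSPV", "LIPV", "RSPV", "RIPV"):
        _circle_pin(
            bc_alpha, bc_beta, mesh, name, rims[name],
            atlas[name]["centre"], atlas[name]["radius"],
            provisional=(a0.alpha, a0.beta),
        )
    if laa_tip is not None:
        c = atlas["LAA_tip"]["centre"]
        bc_alpha.add("LAA_tip", [laa_tip], c[0])
        bc_beta.add("LAA_tip", [laa_tip], c[1])
    return bc_alpha, bc_beta, partition


def _arc_midpoint(mesh, arc: np.ndarray) -> int:
    """Vertex at half the arc length of an open vertex path."""
    pts = mesh.vertices[arc]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return int(arc[int(np.argmin(np.abs(cum - cum[-1] / 2)))])


def build_ra_bcs(
    mesh: SurfaceMesh,
    rims: dict[str, np.ndarray],
    seed_points,
    atlas: dict | None = None,
    raa_tip: int | None = None,
):
    """Boundary conditions for the RA (full-mesh solves).

    ``seed_points`` are two 3D points marking the centres of the lateral and
    septal tricuspid-valve half-rims (the two manual RA landmarks). The IVC
    and SVC rims carry beta = 0 / 1 directly. Alpha winds around the
    chamber: the surface is cut open along a seam of geodesic slits from the
    posterior TV junction to the IVC rim and from the IVC to the SVC rim
    (the boundary paths along which the coordinate is double-valued), and
    the two sides of the seam carry alpha = 0 (lateral side) and 1 (septal
    side). The lateral TV half then sits at low alpha and the septal half at
    high alpha, with the 0/1 jump confined to the seam.
    """
    atlas = {**RA_ATLAS_DEFAULTS, **(atlas or {})}
    for need in ("TV", "SVC", "IVC", "CS"):
        if need not in rims:
            raise KeyError(f"missing rim label {need!r}")
    tv = np.asarray(rims["TV"], dtype=np.int64)
    seed_lat, seed_sept = seed_points
    s_lat = _nearest_loop_vertex(mesh, tv, seed_lat)
    s_sept = _nearest_loop_vertex(mesh, tv, seed_sept)
    i = int(np.flatnonzero(tv == s_lat)[0])
    j = int(np.flatnonzero(tv == s_sept)[0])
    half1, half2 = _split_loop(tv, i, j)
    # junctions between the lateral and septal halves: arc midpoints of the
    # two arcs connecting the seed vertices
    j_a = _arc_midpoint(mesh, half1)
    j_b = _arc_midpoint(mesh, half2)

    svc = np.asarray(rims["SVC"], dtype=np.int64)
    ivc = np.asarray(rims["IVC"], dtype=np.int64)
    svc_c = mesh.vertices[svc].mean(axis=0)

    # the junction nearer the IVC anchors the seam
    d_a = np.linalg.norm(mesh.vertices[j_a] - mesh.vertices[ivc].mean(axis=0))
    d_b = np.linalg.norm(mesh.vertices[j_b] - mesh.vertices[ivc].mean(axis=0))
    j_post = j_a if d_a <= d_b else j_b

    p_ivc_in = _nearest_loop_vertex(mesh, ivc, mesh.vertices[j_post])
    p_ivc_out = _nearest_loop_vertex(mesh, ivc, svc_c)
    p_svc_in = _nearest_loop_vertex(mesh, svc, mesh.vertices[p_ivc_out])

    all_rims = np.concatenate([np.asarray(v) for v in rims.values()])

    def forb_except(*keep):
        f = set(int(v) for v in all_rims)
        for k in keep:
            f.discard(int(k))
        return np.asarray(sorted(f), dtype=np.int64)

    c_tv_ivc = geodesic_path(mesh, j_post, p_ivc_in, forb_except(j_post, p_ivc_in))
    c_ivc_svc = geodesic_path(
        mesh, p_ivc_out, p_svc_in, forb_except(p_ivc_out, p_svc_in)
    )

    bc_beta = BoundaryConditionSet()
    bc_beta.add("IVC", ivc, float(atlas["IVC"]["beta"]))
    bc_beta.add("SVC", svc, float(atlas["SVC"]["beta"]))
    # the TV shares the inferior (beta = 0) edge with the IVC, connected by
    # the TV-IVC seam path; without this beta is non-monotone south of the
    # IVC and the flattening folds there
    bc_beta.add("TV", tv, float(atlas["IVC"]["beta"]))
    bc_beta.add("TV_IVC_path", c_tv_ivc, float(atlas["IVC"]["beta"]))

    bc_alpha = BoundaryConditionSet()
    bc_alpha.seam_path = [c_tv_ivc, c_ivc_svc]
    bc_alpha.seam_side_values = (0.0, 1.0)  # lateral side low, septal high
    bc_alpha.seam_marker = np.asarray(seed_lat, dtype=float)

    a0 = _combined_solve(mesh, bc_alpha, bc_beta, None, check=False)
    _circle_pin(
        bc_alpha, bc_beta, mesh, "CS", rims["CS"],
        atlas["CS"]["centre"], atlas["CS"]["radius"],
        provisional=(a0.alpha, a0.beta),
    )
    if raa_tip is not None:
        c = atlas["RAA_tip"]["centre"]
        bc_alpha.add("RAA_tip", [raa_tip], c[0])
        bc_beta.add("RAA_tip", [raa_tip], c[1])
    return bc_alpha, bc_beta


def _combined_solve(mesh, bc_alpha, bc_beta, partition, check=True) -> UACField:
    if partition is None:
        if bc_alpha.seam_path is not None:
            alpha = solve_with_seam(
                mesh, bc_alpha, bc_alpha.seam_path,
                side_values=bc_alpha.seam_side_values,
                side_marker=bc_alpha.seam_marker,
            )
        else:
            alpha = solve_laplace(mesh, bc_alpha)
        beta = solve_laplace(mesh, bc_beta)
        return UACField(alpha, beta)
    a_post = solve_laplace(mesh, bc_alpha, partition.posterior_triangles)
    a_ant = solve_laplace(mesh, bc_alpha, partition.anterior_triangles)
    b_post = solve_laplace(mesh, bc_beta, partition.posterior_triangles)
    b_ant = solve_laplace(mesh, bc_beta, partition.anterior_triangles)
    # map posterior beta to [0, 0.5] and anterior to [0.5, 1]: the Dirichlet
    # data is already expressed in final coordinates, so combination is a
    # NaN-aware average (shared cut vertices agree by construction)
    if check:
        cut = partition.cut_path
        gap = np.nanmax(np.abs(b_post[cut] - b_ant[cut]))
        if gap > 1e-6:
            raise MeshTopologyError(f"beta discontinuity {gap:.2e} at roof line")
    with np.errstate(invalid="ignore"):
        alpha = np.nanmean(np.stack([a_post, a_ant]), axis=0)
        beta = np.nanmean(np.stack([b_post, b_ant]), axis=0)
    return UACField(alpha, beta)


def count_flipped_triangles(
    mesh: SurfaceMesh, uac: UACField, exclude_vertices=None
) -> tuple[int, int]:
    """(flips, degenerates) of the 2D flattening.

    A flip is a triangle whose signed (alpha, beta) area opposes the
    dominant orientation; degenerates (area ~ 0 relative to the median) are
    counted separately. Triangles touching ``exclude_vertices`` (the seam,
    where the flattening is legitimately double-valued and the per-vertex
    field carries the average of the two sides) are ignored.
    """
    tris = mesh.triangles
    keep = np.ones(len(tris), dtype=bool)
    if exclude_vertices is not None and len(exclude_vertices):
        excl = np.zeros(uac.alpha.shape[0], dtype=bool)
        excl[np.asarray(exclude_vertices, dtype=np.int64)] = True
        keep = ~excl[tris].any(axis=1)
    uv = uac.uv()[tris[keep]]
    det = (uv[:, 1, 0] - uv[:, 0, 0]) * (uv[:, 2, 1] - uv[:, 0, 1]) - (
        uv[:, 2, 0] - uv[:, 0, 0]
    ) * (uv[:, 1, 1] - uv[:, 0, 1])
    scale = float(np.median(np.abs(det)))
    eps = 1e-9 * max(scale, 1e-30)
    degenerate = np.abs(det) <= eps
    pos = int(np.sum(det > eps))
    neg = int(np.sum(det < -eps))
    return min(pos, neg), int(degenerate.sum())


def _untangle(mesh, field_, fixed_mask, seam_mask=None, max_iter: int = 200) -> int:
    """Relax fold-incident free vertices onto convex neighbour averages.

    Harmonic solves with pinned interior structures can fold locally around
    the pins; replacing the (alpha, beta) of fold-incident free vertices by
    the uniform mean of their neighbours (a convex combination, so values
    stay inside [0, 1]) untangles these local folds. Only vertices incident
    to a flipped triangle are touched; seam-incident triangles (double-
    valued by construction) are ignored. Returns how many were modified.
    """
    adj = (mesh.vertex_adjacency() != 0).astype(float)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    uv = field_.uv()
    touched = np.zeros(mesh.n_vertices, dtype=bool)
    tris = mesh.triangles
    consider = np.ones(len(tris), dtype=bool)
    if seam_mask is not None and seam_mask.any():
        consider = ~seam_mask[tris].any(axis=1)
    for _ in range(max_iter):
        d = uv[tris]
        det = (d[:, 1, 0] - d[:, 0, 0]) * (d[:, 2, 1] - d[:, 0, 1]) - (
            d[:, 2, 0] - d[:, 0, 0]
        ) * (d[:, 1, 1] - d[:, 0, 1])
        scale = float(np.median(np.abs(det)))
        eps = 1e-12 * max(scale, 1e-30)
        dominant = 1.0 if np.sum(det > eps) >= np.sum(det < -eps) else -1.0
        bad = (det * dominant < -eps) & consider
        if not bad.any():
            break
        verts = np.unique(tris[bad])
        verts = verts[~fixed_mask[verts]]
        if len(verts) == 0:
            break
        mean = (adj[verts] @ uv) / deg[verts, None]
        uv[verts] = mean
        touched[verts] = True
    field_.alpha = uv[:, 0]
    field_.beta = uv[:, 1]
    return int(touched.sum())


def compute_uac(
    mesh: SurfaceMesh,
    bc_alpha: BoundaryConditionSet,
    bc_beta: BoundaryConditionSet,
    partition: LAPartition | None = None,
    untangle: bool = True,
) -> UACField:
    """Solve the two harmonic coordinates and combine sub-mesh solutions.

    For the LA the beta solves run on the posterior/anterior sub-meshes
    (posterior in [0, 0.5], anterior in [0.5, 1], exact continuity across the
    roof line); the RA solves run on the full mesh with alpha cut along the
    seam meridian. A local untangling pass removes residual folds around the
    pinned structures. Diagnostics record the flipped/degenerate triangle
    counts of the 2D flattening and the number of relaxed vertices.
    """
    field_ = _combined_solve(mesh, bc_alpha, bc_beta, partition)
    if np.isnan(field_.alpha).any() or np.isnan(field_.beta).any():
        raise MeshTopologyError("UAC solve left vertices without coordinates")
    seam_mask = np.zeros(mesh.n_vertices, dtype=bool)
    if bc_alpha.seam_path is not None:
        for p in (bc_alpha.seam_path if isinstance(bc_alpha.seam_path, list)
                  else [bc_alpha.seam_path]):
            seam_mask[np.asarray(p)] = True
    if partition is not None:
        seam_mask[np.asarray(partition.cut_path)] = True
    if seam_mask.any():
        # widen by one ring: the band around a double-valued seam carries
        # side-averaged values and is not part of the regular flattening
        adj = mesh.vertex_adjacency()
        seam_mask = seam_mask | (adj @ seam_mask.astype(float) > 0)
    n_relaxed = 0
    if untangle:
        fixed = np.zeros(mesh.n_vertices, dtype=bool)
        fixed[bc_alpha.nodes] = True
        fixed[bc_beta.nodes] = True
        fixed |= seam_mask
        n_relaxed = _untangle(mesh, field_, fixed, seam_mask)
    seam_vertices = np.flatnonzero(seam_mask)
    flips, degen = count_flipped_triangles(mesh, field_, seam_vertices)
    field_.diagnostics["flipped_triangles"] = flips
    field_.diagnostics["degenerate_triangles"] = degen
    field_.diagnostics["relaxed_vertices"] = n_relaxed
    field_.diagnostics["seam_vertices"] = int(seam_mask.sum())
    eps = 1e-9
    field_.alpha = np.clip(field_.alpha, 0.0, 1.0) if (
        field_.alpha.min() > -eps and field_.alpha.max() < 1 + eps
    ) else field_.alpha
    field_.beta = np.clip(field_.beta, 0.0, 1.0) if (
        field_.beta.min() > -eps and field_.beta.max() < 1 + eps
    ) else field_.beta
    return field_


def laplacian_smoothness(mesh: SurfaceMesh, values: np.ndarray, interior: np.ndarray) -> float:
    """Max |L x| over interior nodes, a harmonicity diagnostic."""
    L = cotangent_laplacian(mesh)
    r = L @ values
    return float(np.max(np.abs(r[interior]))) if len(interior) else 0.0
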