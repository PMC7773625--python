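"""Mesh data model, file I/O and basic surface geometry."""

import numpy as np
import pytest
import trimesh

import atriafib as af
from atriafib.mesh import MeshTopologyError, path_length
from atriafib.io import FormatError

from conftest import make_strip


def annulus_mesh(n=24, r_in=1.0, r_out=2.0):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    inner = np.stack([r_in * np.cos(ang), r_in * np.sin(ang), np.zeros(n)], axis=1)
    outer = np.stack([r_out * np.cos(ang), r_out * np.sin(ang), np.zeros(n)], axis=1)
    verts = np.concatenate([inner, outer])
    tris = []
    for i in range(n):
        j = (i + 1) % n
        tris += [[i, n + i, n + j], [i, n + j, j]]
    return af.SurfaceMesh(verts, np.asarray(tris))


# ---------------------------------------------------------------- file I/O

def test_carp_round_trip_is_bit_exact(tmp_path, la_mesh):
    fib = af.FibreField(
        np.tile([0.0, 0.0, 1.0], (la_mesh.n_triangles, 1))
    )
    # make fibres tangent-irrelevant here: I/O only reproduces numbers
    rng = np.random.default_rng(0)
    v = rng.standard_normal((la_mesh.n_triangles, 3))
    fib = af.FibreField(v / np.linalg.norm(v, axis=1, keepdims=True))
    af.write_mesh(la_mesh, tmp_path / "la", fmt="carp", fibres=fib)
    back, fib2 = af.read_mesh(tmp_path / "la", fmt="carp", with_fibres=True)
    assert np.array_equal(back.vertices, la_mesh.vertices)
    assert np.array_equal(back.triangles, la_mesh.triangles)
    assert np.array_equal(fib2.vectors, fib.vectors)


def test_vtk_round_trip_close(tmp_path, la_mesh):
    rng = np.random.default_rng(1)
    v = rng.standard_normal((la_mesh.n_triangles, 3))
    fib = af.FibreField(v / np.linalg.norm(v, axis=1, keepdims=True))
    af.write_mesh(la_mesh, tmp_path / "la.vtk", fmt="vtk", fibres=fib,
                  point_data={"alpha": np.linspace(0, 1, la_mesh.n_vertices)})
    back, fib2 = af.read_mesh(tmp_path / "la.vtk", fmt="vtk", with_fibres=True)
    assert np.array_equal(back.triangles, la_mesh.triangles)
    assert np.allclose(back.vertices, la_mesh.vertices, atol=1e-6, rtol=1e-6)
    assert np.allclose(fib2.vectors, fib.vectors, atol=1e-6)


def test_single_triangle_carp(tmp_path):
    (tmp_path / "t.pts").write_text("3\n0 0 0\n1 0 0\n0 1 0\n")
    (tmp_path / "t.elem").write_text("1\nTr 0 1 2 1\n")
    mesh = af.read_mesh(tmp_path / "t", fmt="carp")
    assert mesh.n_vertices == 3 and mesh.n_triangles == 1


def test_quad_cell_rejected_with_line(tmp_path):
    (tmp_path / "t.pts").write_text("4\n0 0 0\n1 0 0\n0 1 0\n1 1 0\n")
    (tmp_path / "t.elem").write_text("1\nQd 0 1 2 3 1\n")
    with pytest.raises(FormatError, match=r"elem:2.*Qd"):
        af.read_mesh(tmp_path / "t", fmt="carp")


def test_index_out_of_range_and_scale(tmp_path):
    (tmp_path / "t.pts").write_text("3\n0 0 0\n1000 0 0\n0 1000 0\n")
    (tmp_path / "t.elem").write_text("1\nTr 0 1 5 1\n")
    with pytest.raises(FormatError, match="out of range"):
        af.read_mesh(tmp_path / "t", fmt="carp")
    (tmp_path / "t.elem").write_text("1\nTr 0 1 2 1\n")
    mesh = af.read_mesh(tmp_path / "t", fmt="carp", scale=1e-3)  # um -> mm
    assert mesh.vertices.max() == pytest.approx(1.0)


# ------------------------------------------------------------- rim loops

def test_annulus_has_two_loops():
    loops = af.detect_rims(annulus_mesh())
    assert len(loops) == 2
    assert sorted(len(lp) for lp in loops) == [24, 24]


def test_rim_loops_partition_boundary_edges(la_mesh):
    loops = af.detect_rims(la_mesh)
    be = {tuple(e) for e in la_mesh.boundary_edges()}
    loop_edges = set()
    for lp in loops:
        for a, b in zip(lp, np.roll(lp, -1)):
            loop_edges.add(tuple(sorted((int(a), int(b)))))
    assert loop_edges == be


def test_closed_surface_raises():
    ico = trimesh.creation.icosphere(subdivisions=2)
    mesh = af.SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
    with pytest.raises(MeshTopologyError, match="no boundary"):
        af.detect_rims(mesh)


def test_seed_naming_follows_nearest_loop():
    mesh = annulus_mesh()
    named = af.detect_rims(mesh, {"inner": [0.9, 0, 0], "outer": [2.2, 0, 0]})
    assert np.linalg.norm(mesh.vertices[named["inner"]], axis=1).max() < 1.5
    assert np.linalg.norm(mesh.vertices[named["outer"]], axis=1).min() > 1.5


# ------------------------------------------------------------- geodesics

def test_geodesic_trivial_and_lower_bound(la_mesh):
    assert af.geodesic_path(la_mesh, 7, 7).tolist() == [7]
    path = af.geodesic_path(la_mesh, 0, la_mesh.n_vertices - 1)
    straight = np.linalg.norm(la_mesh.vertices[0] - la_mesh.vertices[-1])
    assert path_length(la_mesh, path) >= straight - 1e-9


def test_geodesic_matches_networkx_oracle():
    import networkx as nx

    mesh = make_strip(10, 5, 9.0, 4.0)  # 50 vertices
    g = nx.Graph()
    edges, _ = mesh.edges_with_counts()
    for a, b in edges:
        w = float(np.linalg.norm(mesh.vertices[a] - mesh.vertices[b]))
        g.add_edge(int(a), int(b), weight=w)
    start, end = 0, mesh.n_vertices - 1
    expect = nx.shortest_path_length(g, start, end, weight="weight")
    path = af.geodesic_path(mesh, start, end)
    assert path_length(mesh, path) == pytest.approx(expect, abs=1e-9)


def test_geodesic_detours_around_forbidden_band():
    mesh = make_strip(21, 7, 20.0, 6.0)
    start, end = 3, mesh.n_vertices - 4
    direct = path_length(mesh, af.geodesic_path(mesh, start, end))
    # forbid a mid-strip band, leaving only the bottom row open
    band = np.flatnonzero(
        (np.abs(mesh.vertices[:, 0] - 10.0) < 0.6) & (mesh.vertices[:, 1] > 0.5)
    )
    detour_path = af.geodesic_path(mesh, start, end, band)
    assert not np.isin(detour_path, band).any()
    assert path_length(mesh, detour_path) > direct


def test_geodesic_disconnected_raises():
    mesh = make_strip(11, 5, 10.0, 4.0)
    wall = np.flatnonzero(np.abs(mesh.vertices[:, 0] - 5.0) < 0.4)
    with pytest.raises(MeshTopologyError, match="disconnected"):
        af.geodesic_path(mesh, 0, mesh.n_vertices - 1, wall)


# ------------------------------------------------- barycentric location

def test_barycentric_centroid_vertex_and_reconstruction():
    rng = np.random.default_rng(0)
    verts = rng.uniform(0, 1, size=(40, 2))
    from scipy.spatial import Delaunay

    tri = Delaunay(verts)
    tris = tri.simplices
    centroid = verts[tris[0]].mean(axis=0)
    ids, w, n_snap = af.barycentric_locate(centroid[None], verts, tris)
    assert n_snap == 0
    assert np.allclose(w[0], 1 / 3, atol=1e-9) or np.allclose(
        verts[tris[ids[0]]].T @ w[0], centroid, atol=1e-12
    )
    vid = tris[5][1]
    ids, w, _ = af.barycentric_locate(verts[vid][None], verts, tris)
    assert w[0].max() == pytest.approx(1.0, abs=1e-9)
    # random interior points reconstruct exactly
    m = 200
    t = rng.integers(0, len(tris), m)
    ww = rng.dirichlet([1, 1, 1], m)
    pts = np.einsum("qk,qkj->qj", ww, verts[tris[t]])
    ids, w, n_snap = af.barycentric_locate(pts, verts, tris)
    rec = np.einsum("qk,qkj->qj", w, verts[tris[ids]])
    assert n_snap == 0
    assert np.max(np.linalg.norm(rec - pts, axis=1)) < 1e-9


def test_barycentric_outside_snaps_with_clamped_weights():
    verts = np.array([[0, 0], [1, 0], [0, 1.0]])
    tris = np.array([[0, 1, 2]])
    ids, w, n_snap = af.barycentric_locate(np.array([[2.0, 2.0]]), verts, tris)
    assert n_snap == 1
    assert ids[0] == 0
    assert w.min() >= 0 and w[0].sum() == pytest.approx(1.0)


# ------------------------------------------------------------ validation

def test_orientation_and_quality_checks(la_mesh):
    la_mesh.validate()
    bad = af.SurfaceMesh(la_mesh.vertices, la_mesh.triangles.copy())
    bad.triangles[0] = bad.triangles[0][[0, 2, 1]]  # flip one triangle
    with pytest.raises(MeshTopologyError, match="orientation"):
        bad.validate()
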