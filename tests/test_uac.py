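"""Laplace solves, boundary conditions and the coordinate construction."""

import numpy as np
import pytest

import atriafib as af
from atriafib.mesh import MeshTopologyError
from atriafib.uac import (
    BoundaryConditionSet,
    build_la_bcs,
    compute_uac,
    cotangent_laplacian,
    solve_laplace,
)
from atriafib.synthetic import default_uac_seeds

from conftest import make_strip


def strip_bc(mesh, left, right):
    bc = BoundaryConditionSet()
    xs = mesh.vertices[:, 0]
    bc.add("left", np.flatnonzero(xs == xs.min()), left)
    bc.add("right", np.flatnonzero(xs == xs.max()), right)
    return bc


def test_strip_solve_matches_linear_closed_form():
    mesh = make_strip(31, 7, 10.0, 2.0)
    x = solve_laplace(mesh, strip_bc(mesh, 0.0, 1.0))
    assert np.max(np.abs(x - mesh.vertices[:, 0] / 10.0)) < 1e-8


def test_sparse_matches_dense_solve():
    mesh = make_strip(16, 8, 10.0, 4.0)  # 128 vertices
    bc = strip_bc(mesh, 0.0, 1.0)
    x_sparse = solve_laplace(mesh, bc)
    # dense oracle: direct solve of the same reduced system
    L = cotangent_laplacian(mesh).toarray()
    nodes, values = bc.nodes, bc.values
    free = np.setdiff1d(np.arange(mesh.n_vertices), nodes)
    x_dense = np.empty(mesh.n_vertices)
    x_dense[nodes] = values
    x_dense[free] = np.linalg.solve(
        L[np.ix_(free, free)], -L[np.ix_(free, nodes)] @ values
    )
    assert np.max(np.abs(x_sparse - x_dense)) < 1e-9


def test_constant_bc_gives_constant_field():
    mesh = make_strip(11, 5)
    x = solve_laplace(mesh, strip_bc(mesh, 0.5, 0.5))
    assert np.allclose(x, 0.5, atol=1e-12)


def test_interior_maximum_principle():
    mesh = make_strip(21, 9, 10.0, 4.0)
    x = solve_laplace(mesh, strip_bc(mesh, 0.0, 1.0))
    xs = mesh.vertices[:, 0]
    interior = (xs > 0) & (xs < 10.0)
    assert x[interior].min() > 0.0 and x[interior].max() < 1.0


def test_empty_bc_and_unreachable_component_raise():
    mesh = make_strip(6, 4)
    with pytest.raises(ValueError, match="empty"):
        solve_laplace(mesh, BoundaryConditionSet())
    # two disjoint strips; bc only on the first
    a = make_strip(5, 3)
    shifted = a.vertices + [0, 10, 0]
    both = af.SurfaceMesh(
        np.concatenate([a.vertices, shifted]),
        np.concatenate([a.triangles, a.triangles + a.n_vertices]),
    )
    bc = BoundaryConditionSet()
    bc.add("one", [0], 0.0)
    bc.add("two", [1], 1.0)
    with pytest.raises(MeshTopologyError, match="components"):
        solve_laplace(both, bc)


def test_bc_sets_are_disjoint_first_wins():
    bc = BoundaryConditionSet()
    bc.add("a", [1, 2, 3], 0.5)
    bc.add("b", [3, 4], 1.0)
    assert 3 in bc.names["a"] and 3 not in bc.names["b"]
    assert dict(zip(bc.nodes, bc.values))[3] == 0.5
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        bc.add("c", [9], 1.5)


# --------------------------------------------------------- LA construction

def test_la_beta_contract(la_mesh, la_spec):
    bc_a, bc_b, part = build_la_bcs(
        la_mesh, la_mesh.rim_labels, default_uac_seeds(la_spec)["MV_septal"],
        laa_tip=la_mesh.landmarks["LAA_tip"],
    )
    uac = compute_uac(la_mesh, bc_a, bc_b, part)
    assert np.allclose(uac.beta[bc_b.names["MV_posterior"]], 0.0)
    assert np.allclose(uac.beta[bc_b.names["MV_anterior"]], 1.0)
    assert np.allclose(uac.beta[part.cut_path], 0.5)
    # roof line separates the mesh into exactly two triangle sets
    assert len(part.posterior_triangles) + len(part.anterior_triangles) == (
        la_mesh.n_triangles
    )
    assert len(part.posterior_triangles) > 0 and len(part.anterior_triangles) > 0


def test_la_structures_land_in_atlas_boxes(la_mesh, la_uac):
    from atriafib.uac import LA_ATLAS_DEFAULTS

    for name in ("RSPV", "RIPV", "LSPV", "LIPV"):
        loop = la_mesh.rim_labels[name]
        ca = la_uac.alpha[loop].mean()
        cb = la_uac.beta[loop].mean()
        a0, b0 = LA_ATLAS_DEFAULTS[name]["centre"]
        assert abs(ca - a0) < 0.05 and abs(cb - b0) < 0.05
    tip = la_mesh.landmarks["LAA_tip"]
    a0, b0 = LA_ATLAS_DEFAULTS["LAA_tip"]["centre"]
    assert la_uac.alpha[tip] == pytest.approx(a0) and la_uac.beta[tip] == pytest.approx(b0)


def test_pinning_follows_labels_not_geometry(la_mesh, la_spec, la_uac):
    """Swapping two PV labels moves their atlas destinations with them."""
    swapped = dict(la_mesh.rim_labels)
    swapped["LSPV"], swapped["LIPV"] = swapped["LIPV"], swapped["LSPV"]
    mesh2 = af.SurfaceMesh(
        la_mesh.vertices.copy(), la_mesh.triangles.copy(),
        rim_labels=swapped, landmarks=dict(la_mesh.landmarks),
        chamber="LA",
    )
    bc_a, bc_b, part = build_la_bcs(
        mesh2, mesh2.rim_labels, default_uac_seeds(la_spec)["MV_septal"]
    )
    uac2 = compute_uac(mesh2, bc_a, bc_b, part)
    from atriafib.uac import LA_ATLAS_DEFAULTS

    loop = swapped["LSPV"]  # geometrically the inferior vein
    assert abs(uac2.beta[loop].mean() - LA_ATLAS_DEFAULTS["LSPV"]["centre"][1]) < 0.05
    # and it differs from where that loop went under correct labels
    assert abs(uac2.beta[loop].mean() - la_uac.beta[loop].mean()) > 0.05


def test_missing_rim_label_raises(la_mesh, la_spec):
    rims = {k: v for k, v in la_mesh.rim_labels.items() if k != "LIPV"}
    with pytest.raises(KeyError, match="LIPV"):
        build_la_bcs(la_mesh, rims, default_uac_seeds(la_spec)["MV_septal"])


def test_uac_values_in_unit_square_and_deterministic(la_mesh, la_uac, la_spec):
    assert la_uac.alpha.min() >= 0 and la_uac.alpha.max() <= 1
    assert la_uac.beta.min() >= 0 and la_uac.beta.max() <= 1
    from atriafib.pipeline import compute_chamber_uac

    again = compute_chamber_uac(la_mesh, default_uac_seeds(la_spec))
    assert np.array_equal(again.alpha, la_uac.alpha)
    assert np.array_equal(again.beta, la_uac.beta)


def test_harmonicity_of_untouched_interior(la_mesh, la_uac, la_spec):
    """Interior vertices not relaxed by untangling satisfy the discrete
    Laplace equation of the (sub-mesh) solves they came from."""
    bc_a, bc_b, part = build_la_bcs(
        la_mesh, la_mesh.rim_labels, default_uac_seeds(la_spec)["MV_septal"],
        laa_tip=la_mesh.landmarks["LAA_tip"],
    )
    uac = compute_uac(la_mesh, bc_a, bc_b, part, untangle=False)
    L = cotangent_laplacian(la_mesh, part.posterior_triangles)
    r = L @ uac.beta
    post_verts = np.unique(la_mesh.triangles[part.posterior_triangles])
    fixed = set(bc_b.nodes.tolist()) | set(part.cut_path.tolist())
    interior = np.array([v for v in post_verts if v not in fixed])
    assert np.max(np.abs(r[interior])) < 1e-8


def test_flattening_mostly_injective(la_mesh, la_uac, ra_mesh, ra_uac):
    """Orientation flips are confined to a small halo around the pinned
    structures and seams (logged in diagnostics)."""
    for mesh, uac in ((la_mesh, la_uac), (ra_mesh, ra_uac)):
        assert uac.diagnostics["flipped_triangles"] < 0.01 * mesh.n_triangles


def test_la_refinement_convergence():
    """Coordinates computed on a finer mesh agree with the coarse solve."""
    from atriafib.pipeline import compute_chamber_uac
    from scipy.interpolate import NearestNDInterpolator

    coarse_spec = af.AnatomySpec(chamber="LA", edge_length=2.5, seed=0)
    fine_spec = af.AnatomySpec(chamber="LA", edge_length=1.5, seed=0)
    cm, _ = af.make_anatomy(coarse_spec)
    fm, _ = af.make_anatomy(fine_spec)
    cu = compute_chamber_uac(cm, default_uac_seeds(coarse_spec))
    fu = compute_chamber_uac(fm, default_uac_seeds(fine_spec))
    interp_a = NearestNDInterpolator(fm.vertices, fu.alpha)
    interp_b = NearestNDInterpolator(fm.vertices, fu.beta)
    da = np.abs(interp_a(cm.vertices) - cu.alpha)
    db = np.abs(interp_b(cm.vertices) - cu.beta)
    assert np.median(da) < 0.02 and np.median(db) < 0.02


def test_ra_cs_pinned(ra_mesh, ra_uac):
    from atriafib.uac import RA_ATLAS_DEFAULTS

    cs = ra_mesh.rim_labels["CS"]
    a0, b0 = RA_ATLAS_DEFAULTS["CS"]["centre"]
    assert abs(ra_uac.alpha[cs].mean() - a0) < 0.05
    assert abs(ra_uac.beta[cs].mean() - b0) < 0.05
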