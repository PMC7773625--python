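"""Fibres in the UAC basis: angles, projection from sample clouds, mapping.

A per-element orthonormal tangent basis (e_alpha, e_beta) is built from the
coordinate gradients. Fibre vectors are expressed as an angle ``theta`` in
[0, pi) measured from the chamber's reference axis: the alpha axis for the
LA (theta ~ 0 lateral-septal, theta ~ pi/2 posterior-anterior) and the beta
axis for the RA (theta ~ 0 IVC-SVC, theta ~ pi/2 lateral-septal).

Because fibres are sense-free (theta and theta+pi identical), every
interpolation or average runs in doubled-angle space: the unit vector
(cos 2*theta, sin 2*theta) is interpolated and the angle halved, which is
continuous across the 0/pi wrap where raw angles are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import (
    FibreField,
    SurfaceMesh,
    VectorSampleCloud,
    barycentric_locate,
)
from .uac import UACField

logger = logging.getLogger(__name__)

__all__ = [
    "UACBasis",
    "UACAngleField",
    "project_fibres_to_surface",
    "compute_uac_basis",
    "fibre_to_angle",
    "angle_to_fibre",
    "map_fibres",
    "vertex_doubled_angles",
]


@dataclass
class UACAngleField:
    """Per-element fibre angle theta in [0, pi) in the UAC basis."""

    theta: np.ndarray
    chamber: str = "LA"

    def __post_init__(self) -> None:
        self.theta = np.mod(np.asarray(self.theta, dtype=float), np.pi)


@dataclass
class UACBasis:
    """Per-element orthonormal tangent pair (e_alpha, e_beta)."""

    e_alpha: np.ndarray
    e_beta: np.ndarray
    degenerate: np.ndarray  # element ids whose gradient was degenerate

    def validate(self, mesh: SurfaceMesh, atol: float = 1e-6) -> None:
        n = mesh.triangle_normals()
        assert np.allclose(np.linalg.norm(self.e_alpha, axis=1), 1, atol=atol)
        assert np.allclose(np.linalg.norm(self.e_beta, axis=1), 1, atol=atol)
        assert np.max(np.abs(np.einsum("ij,ij->i", self.e_alpha, self.e_beta))) < atol
        assert np.max(np.abs(np.einsum("ij,ij->i", self.e_alpha, n))) < atol
        assert np.max(np.abs(np.einsum("ij,ij->i", self.e_beta, n))) < atol


# ----------------------------------------------------------------------
# fibre assignment from vector sample clouds (DT-MRI stand-in)
# ----------------------------------------------------------------------

def project_fibres_to_surface(
    mesh: SurfaceMesh, cloud: VectorSampleCloud
) -> FibreField:
    """Assign each element the nearest sample's vector, projected in-plane.

    The closest cloud sample to the element mid-point supplies the vector,
    which is projected onto the triangle plane and renormalised. If the
    projection vanishes (sample normal to the triangle), the element inherits
    the fibre of its nearest already-resolved neighbour; the replacement
    count is logged.
    """
    tree = cKDTree(cloud.positions)
    centroids = mesh.triangle_centroids()
    _, idx = tree.query(centroids, k=1)
    vec = cloud.vectors[np.atleast_1d(idx)]
    normals = mesh.triangle_normals()
    vec = vec - np.einsum("ij,ij->i", vec, normals)[:, None] * normals
    norms = np.linalg.norm(vec, axis=1)
    ok = norms > 1e-8
    vec[ok] /= norms[ok, None]
    n_replaced = int(np.sum(~ok))
    if n_replaced:
        good = np.flatnonzero(ok)
        bad = np.flatnonzero(~ok)
        ctree = cKDTree(centroids[good])
        _, j = ctree.query(centroids[bad], k=1)
        donor = vec[good[np.atleast_1d(j)]]
        # re-project the donor fibre into each degenerate element's plane
        donor = donor - np.einsum(
            "ij,ij->i", donor, normals[bad]
        )[:, None] * normals[bad]
        dn = np.linalg.norm(donor, axis=1)
        dn[dn < 1e-12] = 1.0
        vec[bad] = donor / dn[:, None]
        logger.info("project_fibres_to_surface: replaced %d degenerate elements",
                    n_replaced)
    return FibreField(vec)


# ----------------------------------------------------------------------
# UAC tangent basis and angles
# ----------------------------------------------------------------------

def _element_gradient(mesh: SurfaceMesh, values: np.ndarray) -> np.ndarray:
    """P1 in-plane gradient of a vertex field, per element (M, 3)."""
    tris = mesh.triangles
    p = mesh.vertices[tris]
    n = mesh.triangle_normals()
    areas = mesh.triangle_areas()
    grad = np.zeros((len(tris), 3))
    for k in range(3):
        # gradient of hat function at vertex k: rotate opposite edge
        e = p[:, (k + 2) % 3] - p[:, (k + 1) % 3]
        gk = np.cross(n, e) / (2.0 * areas)[:, None]
        grad += values[tris[:, k]][:, None] * gk
    return grad


def compute_uac_basis(mesh: SurfaceMesh, uac: UACField) -> UACBasis:
    """Orthonormal tangent basis from the alpha gradient per element.

    ``e_alpha`` is the normalised in-plane gradient of alpha; ``e_beta`` is
    the surface normal crossed with ``e_alpha``, so (e_alpha, e_beta, n) is
    right-handed. Elements with a degenerate gradient inherit the basis of
    the nearest non-degenerate element (count logged).
    """
    ga = _element_gradient(mesh, uac.alpha)
    n = mesh.triangle_normals()
    norms = np.linalg.norm(ga, axis=1)
    ok = norms > 1e-12
    e_a = np.zeros_like(ga)
    e_a[ok] = ga[ok] / norms[ok, None]
    degenerate = np.flatnonzero(~ok)
    if len(degenerate):
        centroids = mesh.triangle_centroids()
        good = np.flatnonzero(ok)
        tree = cKDTree(centroids[good])
        _, j = tree.query(centroids[degenerate], k=1)
        donor = e_a[good[np.atleast_1d(j)]]
        # re-orthogonalise the donated direction against the local normal
        donor = donor - np.einsum(
            "ij,ij->i", donor, n[degenerate]
        )[:, None] * n[degenerate]
        dn = np.linalg.norm(donor, axis=1)
        dn[dn < 1e-12] = 1.0
        e_a[degenerate] = donor / dn[:, None]
        logger.info("compute_uac_basis: %d degenerate gradients replaced",
                    len(degenerate))
    e_b = np.cross(n, e_a)
    return UACBasis(e_a, e_b, degenerate)


def _axes(basis: UACBasis, chamber: str):
    """Reference/orthogonal axis pair for the chamber's angle convention."""
    if chamber == "LA":
        return basis.e_alpha, basis.e_beta
    if chamber == "RA":
        return basis.e_beta, basis.e_alpha
    raise ValueError(f"unknown chamber {chamber!r}")


def fibre_to_angle(
    fibres: FibreField, basis: UACBasis, chamber: str = "LA"
) -> UACAngleField:
    """Angle of each fibre in the UAC basis, wrapped to [0, pi)."""
    ref, orth = _axes(basis, chamber)
    x = np.einsum("ij,ij->i", fibres.vectors, ref)
    y = np.einsum("ij,ij->i", fibres.vectors, orth)
    theta = np.mod(np.arctan2(y, x), np.pi)
    return UACAngleField(theta, chamber)


def angle_to_fibre(
    theta, basis: UACBasis, chamber: str = "LA"
) -> FibreField:
    """Reconstruct tangent unit vectors from UAC angles."""
    if isinstance(theta, UACAngleField):
        theta = theta.theta
    theta = np.asarray(theta, dtype=float)
    ref, orth = _axes(basis, chamber)
    v = np.cos(theta)[:, None] * ref + np.sin(theta)[:, None] * orth
    return FibreField(v / np.linalg.norm(v, axis=1, keepdims=True))


# ----------------------------------------------------------------------
# cross-anatomy mapping
# ----------------------------------------------------------------------

def vertex_doubled_angles(
    mesh: SurfaceMesh, theta: np.ndarray, exclude_elements=None
) -> np.ndarray:
    """Per-vertex doubled-angle unit vectors averaged over incident elements.

    Returns an (N, 2) array of (cos 2*theta, sin 2*theta); vertices whose
    incident elements are all excluded get a zero vector.
    """
    d = np.stack([np.cos(2 * theta), np.sin(2 * theta)], axis=1)
    if exclude_elements is not None and len(exclude_elements):
        d = d.copy()
        d[np.asarray(exclude_elements, dtype=np.int64)] = 0.0
    acc = np.zeros((mesh.n_vertices, 2))
    for k in range(3):
        np.add.at(acc, mesh.triangles[:, k], d)
    norms = np.linalg.norm(acc, axis=1)
    ok = norms > 1e-12
    acc[ok] /= norms[ok, None]
    acc[~ok] = 0.0
    return acc


def _seam_elements(mesh: SurfaceMesh, uac: UACField) -> np.ndarray:
    """Elements whose UAC triangle is flipped or degenerate.

    These straddle the lateral/septal seam (or a pinned rim) where the
    flattening is not locally injective; they are excluded as interpolation
    sources and back-filled from their nearest regular neighbour.
    """
    uv = uac.uv()[mesh.triangles]
    det = (uv[:, 1, 0] - uv[:, 0, 0]) * (uv[:, 2, 1] - uv[:, 0, 1]) - (
        uv[:, 2, 0] - uv[:, 0, 0]
    ) * (uv[:, 1, 1] - uv[:, 0, 1])
    dominant = 1.0 if np.sum(det > 0) >= np.sum(det < 0) else -1.0
    area_scale = np.median(np.abs(det))
    bad = (det * dominant) <= 1e-6 * area_scale
    return np.flatnonzero(bad)


def element_uac_centroids(mesh: SurfaceMesh, uac: UACField) -> np.ndarray:
    return uac.uv()[mesh.triangles].mean(axis=1)


def map_fibres(
    source_mesh: SurfaceMesh,
    source_uac: UACField,
    source_fibres: FibreField,
    target_mesh: SurfaceMesh,
    target_uac: UACField,
    chamber: str = "LA",
) -> tuple[FibreField, dict]:
    """Map a fibre field from a source anatomy to a target anatomy via UAC.

    The source field is expressed as UAC angles; target element centroids are
    located in the source's UAC-space triangulation (source connectivity,
    seam-straddling triangles excluded) and the doubled-angle unit vector is
    barycentrically interpolated, halved, and reconstructed as a 3D tangent
    vector in the target basis. Target elements that land on excluded source
    triangles, or whose own flattening straddles the seam, take the value of
    their nearest regular neighbour.

    Returns the mapped field and a report dict (snap/seam counts).
    """
    if source_mesh.chamber and target_mesh.chamber and (
        source_mesh.chamber != target_mesh.chamber
    ):
        raise ValueError("source and target chambers differ")
    src_basis = compute_uac_basis(source_mesh, source_uac)
    src_theta = fibre_to_angle(source_fibres, src_basis, chamber).theta

    excluded = _seam_elements(source_mesh, source_uac)
    vd = vertex_doubled_angles(source_mesh, src_theta, exclude_elements=excluded)

    tgt_centroids = element_uac_centroids(target_mesh, target_uac)
    keep = np.ones(source_mesh.n_triangles, dtype=bool)
    keep[excluded] = False
    kept_tris = source_mesh.triangles[keep]
    if len(kept_tris) == 0:
        raise ValueError("no usable source triangles after seam exclusion")
    tri_ids, weights, n_snapped = barycentric_locate(
        tgt_centroids, source_uac.uv(), kept_tris
    )
    d_interp = np.einsum("qk,qkj->qj", weights, vd[kept_tris[tri_ids]])
    norms = np.linalg.norm(d_interp, axis=1)
    resolved = norms > 1e-9
    theta_t = np.zeros(target_mesh.n_triangles)
    theta_t[resolved] = 0.5 * np.arctan2(
        d_interp[resolved, 1], d_interp[resolved, 0]
    )

    tgt_seam = _seam_elements(target_mesh, target_uac)
    needs_fill = ~resolved
    needs_fill[tgt_seam] = True
    n_seam = int(needs_fill.sum())
    if n_seam:
        good = np.flatnonzero(~needs_fill)
        if len(good) == 0:
            raise ValueError("no regular target elements to back-fill from")
        bad = np.flatnonzero(needs_fill)
        tree = cKDTree(tgt_centroids[good])
        _, j = tree.query(tgt_centroids[bad], k=1)
        theta_t[bad] = theta_t[good[np.atleast_1d(j)]]
        logger.info("map_fibres: %d target elements back-filled near seam", n_seam)

    tgt_basis = compute_uac_basis(target_mesh, target_uac)
    mapped = angle_to_fibre(np.mod(theta_t, np.pi), tgt_basis, chamber)
    report = {
        "snapped_points": int(n_snapped),
        "source_seam_elements": int(len(excluded)),
        "target_backfilled_elements": n_seam,
    }
    return mapped, report
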