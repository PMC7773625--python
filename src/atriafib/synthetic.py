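"""Idealised synthetic atrial anatomies and fibre fields.

The generator produces ellipsoidal LA/RA shells with circular rim openings
(four pulmonary veins + mitral valve for the LA; SVC/IVC/tricuspid/coronary
sinus for the RA), an appendage bump, smooth per-case shape perturbations,
and fibre fields that follow a smooth regional angle pattern in UAC space
with seeded wrapped-normal perturbations. Every downstream stage of the
pipeline is testable on these meshes without any imaging data.

Randomness uses ``numpy.random.default_rng`` (PCG64); identical seeds give
identical meshes and fields across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import trimesh

from .mesh import FibreField, SurfaceMesh, VectorSampleCloud, detect_rims
from .uac import UACField

__all__ = [
    "AnatomySpec",
    "FibrePatternSpec",
    "make_anatomy",
    "make_fibre_field",
    "make_vector_cloud",
    "default_uac_seeds",
]


def _sph_dir(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    th = np.deg2rad(polar_deg)
    ph = np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


@dataclass
class AnatomySpec:
    """Parameters of one synthetic atrial shell.

    Rim openings are placed on the unit sphere by (polar, azimuth, angular
    radius) in degrees; the shell is an ellipsoid with the given radii (mm).
    The +y hemisphere is posterior, -z inferior (valve), +x lateral for the
    LA and +x lateral for the RA as well.
    """

    chamber: str = "LA"
    radii: tuple = (35.0, 30.0, 28.0)
    rims: dict = field(default_factory=dict)
    appendage: tuple | None = None  # polar, azimuth, height mm, width deg
    edge_length: float = 1.0
    shape_noise: float = 0.0  # relative radial amplitude of per-case perturbation
    seed: int = 0
    epi_offset: float = 0.5  # mm, synthetic epicardial shell offset

    def __post_init__(self) -> None:
        if self.edge_length <= 0:
            raise ValueError("edge length must be positive")
        if not self.rims:
            self.rims = dict(
                LA_RIM_DEFAULTS if self.chamber == "LA" else RA_RIM_DEFAULTS
            )
        if self.appendage is None:
            # LA appendage anterolateral-superior; RA appendage anterolateral,
            # clear of the alpha seam meridian (anterior TV junction)
            self.appendage = (
                (55.0, -55.0, 6.0, 18.0) if self.chamber == "LA"
                else (62.0, -40.0, 5.0, 16.0)
            )

    def with_(self, **kw) -> "AnatomySpec":
        return replace(self, **kw)


LA_RIM_DEFAULTS = {
    "MV": (180.0, 0.0, 35.0),
    "RSPV": (55.0, 125.0, 10.0),
    "RIPV": (92.0, 130.0, 10.0),
    "LSPV": (55.0, 55.0, 10.0),
    "LIPV": (92.0, 50.0, 10.0),
}

RA_RIM_DEFAULTS = {
    "TV": (180.0, 0.0, 35.0),
    "SVC": (18.0, 90.0, 12.0),
    "IVC": (118.0, 90.0, 12.0),
    "CS": (118.0, 168.0, 6.0),
}


def _subdivisions_for_edge(mean_radius: float, target_edge: float) -> int:
    # icosphere at subdivision s has 20 * 4**s faces over area 4 pi r^2
    for s in range(2, 8):
        face_area = 4.0 * np.pi * mean_radius**2 / (20 * 4**s)
        edge = np.sqrt(4.0 * face_area / np.sqrt(3.0))
        if edge <= target_edge:
            return s
    return 7


def _check_rim_overlap(rims: dict, margin_deg: float = 4.0) -> None:
    names = list(rims)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            da = _sph_dir(*rims[a][:2])
            db = _sph_dir(*rims[b][:2])
            sep = np.rad2deg(np.arccos(np.clip(da @ db, -1, 1)))
            if sep < rims[a][2] + rims[b][2] + margin_deg:
                raise ValueError(f"rim openings {a!r} and {b!r} overlap")


def _vertex_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p = vertices[triangles]
    fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # area-weighted
    vn = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(vn, triangles[:, k], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    norms[norms < 1e-14] = 1.0
    return vn / norms


def make_anatomy(spec: AnatomySpec) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Build the endocardial and epicardial shells for a spec.

    The epicardial shell is the endocardial one offset ``spec.epi_offset``
    mm along vertex normals with identical connectivity and rim labels.
    Deterministic for a fixed ``spec.seed``.
    """
    _check_rim_overlap(spec.rims)
    rng = np.random.default_rng(spec.seed)
    mean_radius = float(np.mean(spec.radii))
    sub = _subdivisions_for_edge(mean_radius, spec.edge_length)
    ico = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
    dirs = np.asarray(ico.vertices, dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    faces = np.asarray(ico.faces, dtype=np.int64)

    # smooth per-case radial perturbation: a few random long-wavelength lobes
    r = np.ones(len(dirs))
    if spec.shape_noise > 0:
        n_lobes = 6
        axes = rng.normal(size=(n_lobes, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        freqs = rng.uniform(1.5, 3.5, size=n_lobes)
        phases = rng.uniform(0, 2 * np.pi, size=n_lobes)
        amps = rng.normal(size=n_lobes) / n_lobes
        for ax, f, ph, am in zip(axes, freqs, phases, amps):
            r += spec.shape_noise * am * np.cos(f * np.pi * (dirs @ ax) + ph)

    # appendage bump
    app_dir = _sph_dir(spec.appendage[0], spec.appendage[1])
    gamma = np.arccos(np.clip(dirs @ app_dir, -1, 1))
    width = np.deg2rad(spec.appendage[3])
    r += (spec.appendage[2] / mean_radius) * np.exp(-((gamma / width) ** 2))

    vertices = dirs * r[:, None] * np.asarray(spec.radii)[None, :]

    # open the rims: drop faces fully inside each angular cap
    inside_any = np.zeros(len(dirs), dtype=bool)
    for name, (polar, azim, rho) in spec.rims.items():
        d = _sph_dir(polar, azim)
        ang = np.arccos(np.clip(dirs @ d, -1, 1))
        inside_any |= ang < np.deg2rad(rho)
    drop = inside_any[faces].all(axis=1)
    faces = faces[~drop]
    used = np.unique(faces)
    remap = -np.ones(len(vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    vertices = vertices[used]
    dirs = dirs[used]
    faces = remap[faces]

    mesh = SurfaceMesh(vertices, faces, chamber=spec.chamber, layer="endo")
    mesh.orient_outward()

    seed_points = {
        name: _sph_dir(polar, azim) * np.asarray(spec.radii)
        for name, (polar, azim, rho) in spec.rims.items()
    }
    mesh.rim_labels = detect_rims(mesh, seed_points)
    if len(mesh.rim_labels) != len(spec.rims) or (
        len({tuple(v[:3]) for v in map(sorted, mesh.rim_labels.values())})
        != len(spec.rims)
    ):
        raise ValueError("rim naming collapsed two openings; adjust the anatomy spec")

    tip_name = "LAA_tip" if spec.chamber == "LA" else "RAA_tip"
    mesh.landmarks[tip_name] = int(np.argmax(dirs @ app_dir))

    epi_vertices = mesh.vertices + spec.epi_offset * _vertex_normals(
        mesh.vertices, mesh.triangles
    )
    epi = SurfaceMesh(
        epi_vertices,
        mesh.triangles.copy(),
        rim_labels={k: v.copy() for k, v in mesh.rim_labels.items()},
        landmarks=dict(mesh.landmarks),
        chamber=spec.chamber,
        layer="epi",
    )
    return mesh, epi


def default_uac_seeds(spec: AnatomySpec) -> dict[str, np.ndarray]:
    """Manual-landmark stand-ins for the UAC construction.

    LA: one point marking the septal end of the MV rim. RA: two points
    marking the lateral and septal TV junctions.
    """
    radii = np.asarray(spec.radii)
    if spec.chamber == "LA":
        polar = 180.0 - spec.rims["MV"][2]
        return {"MV_septal": _sph_dir(polar, 180.0) * radii}
    polar = 180.0 - spec.rims["TV"][2]
    return {
        "TV_lateral": _sph_dir(polar, 0.0) * radii,
        "TV_septal": _sph_dir(polar, 180.0) * radii,
    }


# ----------------------------------------------------------------------
# fibre patterns
# ----------------------------------------------------------------------

def _la_default_angle(alpha, beta):
    # posterior-anterior fibres on the roof band, lateral-septal elsewhere
    return (np.pi / 2) * np.exp(-((beta - 0.5) ** 2) / (2 * 0.12**2))


def _ra_default_angle(alpha, beta):
    # IVC-SVC (crista-like) base pattern with a lateral pectinate band
    return (np.pi / 2) * np.exp(-((alpha - 0.2) ** 2) / (2 * 0.18**2))


_PATTERNS: dict[str, Callable] = {
    "la_default": _la_default_angle,
    "ra_default": _ra_default_angle,
}


@dataclass
class FibrePatternSpec:
    """Smooth target angle theta(alpha, beta) plus perturbation parameters.

    ``kappa`` is the perturbation concentration: fibre angles are perturbed
    by wrapped-normal noise on the *doubled* angle with standard deviation
    ``1/kappa`` radians (kappa = 0 or inf disables noise cleanly at the two
    extremes; see docs). Inside ``noise_region`` (an (amin, amax, bmin,
    bmax) box) the concentration drops to ``noise_region_kappa``, emulating
    a structure (e.g. the roof) whose fibre direction varies strongly
    between subjects.
    """

    angle: Callable | str = "la_default"
    kappa: float = np.inf
    noise_region: tuple | None = None
    noise_region_kappa: float | None = None

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if isinstance(self.angle, str):
            self.angle = _PATTERNS[self.angle]

    def target_theta(self, alpha, beta) -> np.ndarray:
        return np.mod(self.angle(np.asarray(alpha), np.asarray(beta)), np.pi)


def make_fibre_field(
    mesh: SurfaceMesh,
    uac: UACField,
    pattern: FibrePatternSpec,
    seed: int = 0,
) -> FibreField:
    """Fibre field following a UAC angle pattern with seeded perturbation.

    With no noise the recomputed UAC angle of each element equals the
    pattern angle at its UAC centroid exactly (up to float rounding).
    """
    from .mapping import angle_to_fibre, compute_uac_basis

    uv = uac.uv()[mesh.triangles].mean(axis=1)
    theta = pattern.target_theta(uv[:, 0], uv[:, 1])
    kappa = np.full(len(theta), float(pattern.kappa))
    if pattern.noise_region is not None and pattern.noise_region_kappa is not None:
        amin, amax, bmin, bmax = pattern.noise_region
        in_box = (
            (uv[:, 0] >= amin) & (uv[:, 0] <= amax)
            & (uv[:, 1] >= bmin) & (uv[:, 1] <= bmax)
        )
        kappa[in_box] = float(pattern.noise_region_kappa)
    with np.errstate(divide="ignore"):
        sigma2 = np.where(kappa > 0, 1.0 / kappa, 0.0)  # doubled-angle std
    if np.any(sigma2 > 0):
        rng = np.random.default_rng(seed)
        theta = theta + 0.5 * sigma2 * rng.standard_normal(len(theta))
    basis = compute_uac_basis(mesh, uac)
    return angle_to_fibre(np.mod(theta, np.pi), basis, mesh.chamber or "LA")


def make_vector_cloud(
    mesh: SurfaceMesh, fibres: FibreField, pitch: float = 0.4
) -> VectorSampleCloud:
    """Regular-grid samples near the surface carrying the nearest element's
    fibre vector — an emulation of reconstructed DT-MRI eigenvector output
    at the given voxel pitch (mm)."""
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    from scipy.spatial import cKDTree

    centroids = mesh.triangle_centroids()
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    axes = [np.arange(lo[k], hi[k] + pitch, pitch) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    tree = cKDTree(centroids)
    dist, idx = tree.query(grid, k=1)
    edge = float(np.median(np.linalg.norm(
        mesh.vertices[mesh.triangles[:, 0]] - mesh.vertices[mesh.triangles[:, 1]],
        axis=1,
    )))
    keep = dist <= max(pitch, edge)
    if not keep.any():
        keep = dist <= dist.min() + 1e-9  # degenerate pitch: keep closest point
    return VectorSampleCloud(grid[keep], fibres.vectors[idx[keep]])
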