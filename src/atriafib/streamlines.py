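"""Fibre streamlines traced in 2D UAC space and lifted to 3D.

Streamlines integrate the sense-free unit direction (cos theta, sin theta)
of the fibre angle field in the coordinate square with a fixed-step RK4
scheme; the local angle is barycentric doubled-angle interpolation of the
per-vertex field, and the sign of the direction at each evaluation is chosen
to continue the previous step (fields with no sense cannot be integrated
with a global sign). Integration runs in both directions from each seed.

Tracing in coordinate space ignores the metric distortion of the flattening
(the 3D image of a regular 2D streamline set is not arc-length regular);
the lift to 3D splits polylines where they cross the lateral/septal seam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh, _bary_weights_2d, barycentric_locate
from .mapping import _seam_elements, vertex_doubled_angles
from .uac import UACField

logger = logging.getLogger(__name__)

__all__ = ["Streamline", "trace_streamlines", "thin_streamlines", "streamlines_to_3d"]


@dataclass
class Streamline:
    points: np.ndarray  # (P, 2) in UAC
    seed_id: int

    def __len__(self) -> int:
        return len(self.points)

    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


class _AngleSampler:
    """Doubled-angle interpolation of a per-element theta field in UAC.

    The triangle arrays and the centroid k-d tree are built once; lookups
    check the nearest candidate triangles directly (tracing makes hundreds
    of thousands of single-point queries).
    """

    def __init__(self, mesh: SurfaceMesh, uac: UACField, theta: np.ndarray):
        excluded = _seam_elements(mesh, uac)
        keep = np.ones(mesh.n_triangles, dtype=bool)
        keep[excluded] = False
        self.tris = mesh.triangles[keep]
        self.uv = uac.uv()
        self.vd = vertex_doubled_angles(mesh, theta, exclude_elements=excluded)
        self.tri_xy = self.uv[self.tris]
        self.vert_vd = self.vd[self.tris]  # (M, 3, 2)
        self.centroids = self.tri_xy.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self._k = min(8, len(self.centroids))

    def direction(self, p: np.ndarray):
        """Doubled-angle vector at point p, or None if unlocatable."""
        _, cand = self.tree.query(p, k=self._k)
        cand = np.atleast_1d(cand)
        w = _bary_weights_2d(
            np.broadcast_to(p, (len(cand), 2)), self.tri_xy[cand]
        )
        inside = np.flatnonzero(w.min(axis=1) >= -1e-9)
        if len(inside) == 0:
            return None
        i = int(inside[0])
        d = w[i] @ self.vert_vd[cand[i]]
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            return None
        return d / norm


def _halve(d2: np.ndarray) -> np.ndarray:
    th = 0.5 * np.arctan2(d2[1], d2[0])
    return np.array([np.cos(th), np.sin(th)])


def trace_streamlines(
    theta: np.ndarray,
    mesh: SurfaceMesh,
    uac: UACField,
    n_seeds: int = 10000,
    step: float = 0.005,
    max_steps: int = 2000,
    seed: int = 0,
) -> list[Streamline]:
    """Bidirectional RK4 streamlines from random seeds in the unit square.

    Termination: leaving the unit square, an unlocatable point (hole or
    seam), or ``max_steps`` per direction. Deterministic for a fixed seed.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    theta = np.asarray(getattr(theta, "theta", theta), dtype=float)
    sampler = _AngleSampler(mesh, uac, theta)
    rng = np.random.default_rng(seed)
    seeds = rng.uniform(0.0, 1.0, size=(n_seeds, 2))
    out: list[Streamline] = []

    def in_square(p):
        return 0.0 <= p[0] <= 1.0 and 0.0 <= p[1] <= 1.0

    def rk4_dir(p, prev):
        """One oriented RK4 step from p, continuing direction ``prev``."""

        def f(q, ref):
            d2 = sampler.direction(q)
            if d2 is None:
                return None
            v = _halve(d2)
            return v if v @ ref >= 0 else -v

        k1 = f(p, prev)
        if k1 is None:
            return None
        k2 = f(p + 0.5 * step * k1, k1)
        if k2 is None:
            return None
        k3 = f(p + 0.5 * step * k2, k2)
        if k3 is None:
            return None
        k4 = f(p + step * k3, k3)
        if k4 is None:
            return None
        return p + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    for sid, p0 in enumerate(seeds):
        d2 = sampler.direction(p0)
        if d2 is None:
            continue
        v0 = _halve(d2)
        halves = []
        for sign in (+1.0, -1.0):
            pts = [p0]
            prev = sign * v0
            for _ in range(max_steps):
                nxt = rk4_dir(pts[-1], prev)
                if nxt is None or not in_square(nxt):
                    break
                prev = nxt - pts[-1]
                norm = np.linalg.norm(prev)
                if norm < 1e-12:
                    break
                prev = prev / norm
                pts.append(nxt)
            halves.append(pts)
        back = halves[1][1:][::-1]
        points = np.asarray(back + halves[0], dtype=float)
        if len(points) >= 2:
            out.append(Streamline(points, sid))
    return out


def thin_streamlines(streamlines, spacing: float) -> list[Streamline]:
    """Greedy regular-coverage subset, longest first.

    A candidate is kept iff all of its points are at least ``spacing`` (in
    UAC) from every point of every kept streamline. Deterministic (ties by
    seed id).
    """
    if spacing < 0:
        raise ValueError("spacing must be >= 0")
    order = sorted(streamlines, key=lambda s: (-s.length(), s.seed_id))
    if spacing == 0:
        return order
    kept: list[Streamline] = []
    kept_points: list[np.ndarray] = []
    tree = None
    for s in order:
        if tree is None:
            ok = True
        else:
            d, _ = tree.query(s.points, k=1)
            ok = bool(np.min(d) >= spacing)
        if ok:
            kept.append(s)
            kept_points.append(s.points)
            tree = cKDTree(np.concatenate(kept_points))
    return kept


def streamlines_to_3d(
    streamlines,
    mesh: SurfaceMesh,
    uac: UACField,
) -> list[np.ndarray]:
    """Lift 2D streamlines to 3D polylines by barycentric interpolation.

    Polylines are split where consecutive points land across the seam
    (3D jump much longer than the local 2D step implies); unlocatable
    points are dropped with a logged count.
    """
    tris = mesh.triangles
    seam = _seam_elements(mesh, uac)
    keep = np.ones(mesh.n_triangles, dtype=bool)
    keep[seam] = False
    kept_tris = tris[keep]
    uv = uac.uv()
    out: list[np.ndarray] = []
    n_dropped = 0
    n_split = 0
    for s in streamlines:
        tri_ids, w, snapped = barycentric_locate(s.points, uv, kept_tris)
        pts3 = np.einsum("qk,qkj->qj", w, mesh.vertices[kept_tris[tri_ids]])
        # points that had to snap far in UAC are unlocatable -> dropped
        recon = np.einsum("qk,qkj->qj", w, uv[kept_tris[tri_ids]])
        good = np.linalg.norm(recon - s.points, axis=1) < 0.01
        n_dropped += int((~good).sum())
        # a 3D jump far out of proportion to the 2D step means the seam
        # was crossed: split the polyline there instead of bridging it
        step2 = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
        step3 = np.linalg.norm(np.diff(pts3, axis=0), axis=1)
        pos = step2 > 1e-12
        scale = float(np.median(step3[pos] / step2[pos])) if pos.any() else 1.0
        jump = np.zeros(len(pts3), dtype=bool)
        jump[1:] = step3 > 10.0 * max(scale, 1e-9) * np.maximum(step2, 1e-12)
        n_split += int(jump.sum())
        segment: list[np.ndarray] = []
        for i in range(len(pts3)):
            if not good[i] or jump[i]:
                if len(segment) >= 2:
                    out.append(np.asarray(segment))
                segment = [pts3[i]] if good[i] else []
            else:
                segment.append(pts3[i])
        if len(segment) >= 2:
            out.append(np.asarray(segment))
    if n_dropped:
        logger.info("streamlines_to_3d: dropped %d unlocatable points", n_dropped)
    logger.info("streamlines_to_3d: %d seam splits", n_split)
    return out
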