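"""Spiral-wave initial conditions, phase singularities and density maps.

Fibrillation-like activity is started from initial conditions encoding four
Archimedean spiral re-entries in UAC space (two posterior, two anterior,
equal spacing, alternating chirality), identical on both layers of a
bilayer. Voltage phase is computed by delay embedding; phase singularities
(PS) are the triangles where the vertex phase winds by +-2 pi, reported in
UAC so that maps from different anatomies and layers are directly
comparable. PS dwell histograms over the coordinate square ("PS density
maps") are the arrhythmia comparison currency; two maps are compared with
the 2D Pearson correlation over grid cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ep import MonodomainSystem, run_monodomain
from .mesh import SurfaceMesh
from .uac import UACField

logger = logging.getLogger(__name__)

__all__ = [
    "SpiralICSpec",
    "PSEvent",
    "PSDensityMap",
    "spiral_initial_state",
    "compute_phase",
    "detect_ps",
    "ps_density",
    "mean_ps_count",
    "density_correlation",
    "af_experiment",
]


@dataclass
class SpiralICSpec:
    """Archimedean-spiral pseudo-activation-time initial condition.

    ``cores`` is a list of (alpha, beta, chirality) with chirality +-1;
    adjacent cores alternate chirality (validated). ``cycle`` (ms) is the
    re-entry period encoded in the field and ``pitch`` the Archimedean
    radial pitch in UAC units per radian.
    """

    cores: tuple = (
        (0.25, 0.25, +1),
        (0.75, 0.25, -1),
        (0.25, 0.75, -1),
        (0.75, 0.75, +1),
    )
    cycle: float = 180.0
    pitch: float = 0.08

    def __post_init__(self) -> None:
        for a, b, chi in self.cores:
            if not (0 <= a <= 1 and 0 <= b <= 1):
                raise ValueError("spiral cores must lie in the unit square")
            if chi not in (-1, +1):
                raise ValueError("chirality must be +-1")
        if len(self.cores) > 1:
            xy = np.asarray([(a, b) for a, b, _ in self.cores])
            chis = np.asarray([c for _, _, c in self.cores])
            d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            nn = np.argmin(d, axis=1)
            if np.any(chis[nn] == chis):
                raise ValueError("adjacent spirals must have opposite chirality")


def spiral_activation_field(spec: SpiralICSpec, uv: np.ndarray) -> np.ndarray:
    """Pseudo-activation time t0(alpha, beta) in [0, cycle).

    Each point uses its nearest core: t0 = (cycle / 2 pi) (chi * phi +
    r / pitch) mod cycle, an Archimedean spiral wavefront rotating with the
    core's chirality.
    """
    cores = np.asarray([(a, b) for a, b, _ in spec.cores], dtype=float)
    chis = np.asarray([c for _, _, c in spec.cores], dtype=float)
    d = uv[:, None, :] - cores[None, :, :]
    r = np.linalg.norm(d, axis=2)
    nearest = np.argmin(r, axis=1)
    rows = np.arange(len(uv))
    dx = d[rows, nearest]
    phi = np.arctan2(dx[:, 1], dx[:, 0])
    t0 = (spec.cycle / (2 * np.pi)) * (
        chis[nearest] * phi + r[rows, nearest] / spec.pitch
    )
    return np.mod(t0, spec.cycle)


def _ap_template(membrane, cycle: float, dt: float = 0.05):
    """One steady propagated-AP-shaped trajectory of the membrane states.

    A single cell is paced twice at the encoded cycle length and the second
    cycle is recorded, giving state-vs-time-since-upstroke curves used to
    seed the tissue.
    """
    st = membrane.initial_state(1)
    n = int(round(2 * cycle / dt))
    rec_from = int(round(cycle / dt))
    ts, vs, hs = [], [], []
    for i in range(n):
        t = i * dt
        stim = 0.3 if (t % cycle) < 2.0 else 0.0
        membrane.step(st, dt, stim)
        if i >= rec_from:
            ts.append(t - cycle)
            vs.append(st["v"][0])
            hs.append(st["h"][0])
    return np.asarray(ts), np.asarray(vs), np.asarray(hs)


def spiral_initial_state(
    system: MonodomainSystem,
    membrane,
    spec: SpiralICSpec,
    uac: UACField,
) -> dict[str, np.ndarray]:
    """Node states encoding the spiral field; identical on all layers."""
    ts, vs, hs = _ap_template(membrane, spec.cycle)
    uv = uac.uv()
    t0 = spiral_activation_field(spec, uv)
    elapsed = np.mod(spec.cycle - t0, spec.cycle)
    v = np.interp(elapsed, ts, vs)
    h = np.interp(elapsed, ts, hs)
    reps = system.n_nodes // len(uv)
    if reps * len(uv) != system.n_nodes:
        raise ValueError("UAC field does not tile the system's node count")
    return {"v": np.tile(v, reps), "h": np.tile(h, reps)}


# ----------------------------------------------------------------------
# phase and phase singularities
# ----------------------------------------------------------------------

def compute_phase(
    times: np.ndarray, voltages: np.ndarray, tau: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Delay-embedding phase per node.

    phase(t) = atan2(V(t - tau) - Vbar, V(t) - Vbar) with the per-node trace
    mean Vbar. Returns (phase_times, phase) where the first ``tau`` of the
    trace is consumed by the delay. Nodes with negligible amplitude are
    flagged NaN.
    """
    times = np.asarray(times, dtype=float)
    voltages = np.asarray(voltages, dtype=float)
    if len(times) < 3:
        raise ValueError("trace too short for phase computation")
    cadence = float(np.median(np.diff(times)))
    lag = max(1, int(round(tau / cadence)))
    vbar = voltages.mean(axis=0)
    x = voltages[lag:] - vbar
    y = voltages[:-lag] - vbar
    phase = np.arctan2(y, x)
    amp = voltages.max(axis=0) - voltages.min(axis=0)
    phase[:, amp < 1e-6] = np.nan
    return times[lag:], phase


@dataclass
class PSEvent:
    time: float
    alpha: float
    beta: float
    charge: int


def detect_ps(
    phase_snapshot: np.ndarray,
    mesh: SurfaceMesh,
    uac: UACField,
    time: float = 0.0,
    tol: float = np.pi,
) -> list[PSEvent]:
    """Phase singularities of one snapshot.

    A triangle hosts a PS when the oriented sum of wrapped vertex-phase
    differences around it is +-2 pi (the sum is an exact multiple of 2 pi,
    so any tolerance below 2 pi identifies it). Charge is the winding sign;
    the location is the face centroid in UAC.
    """
    ph = np.asarray(phase_snapshot, dtype=float)
    tris = mesh.triangles
    p = ph[tris]
    ok = np.isfinite(p).all(axis=1)

    def wrap(d):
        return np.mod(d + np.pi, 2 * np.pi) - np.pi

    w = (
        wrap(p[:, 1] - p[:, 0])
        + wrap(p[:, 2] - p[:, 1])
        + wrap(p[:, 0] - p[:, 2])
    )
    hit = np.flatnonzero(ok & (np.abs(w) > tol))
    uv = uac.uv()[tris].mean(axis=1)
    # a core lying close to an edge can register in two adjacent faces;
    # merge vertex-adjacent detections of equal charge into one event
    events: list[PSEvent] = []
    used = np.zeros(len(hit), dtype=bool)
    vert_sets = [set(int(v) for v in tris[i]) for i in hit]
    for a in range(len(hit)):
        if used[a]:
            continue
        group = [a]
        used[a] = True
        frontier = [a]
        while frontier:
            cur = frontier.pop()
            for b in range(len(hit)):
                if used[b] or np.sign(w[hit[b]]) != np.sign(w[hit[cur]]):
                    continue
                if vert_sets[cur] & vert_sets[b]:
                    used[b] = True
                    group.append(b)
                    frontier.append(b)
        loc = uv[hit[group]].mean(axis=0)
        events.append(
            PSEvent(time, float(loc[0]), float(loc[1]),
                    int(np.sign(w[hit[a]])))
        )
    return events


@dataclass
class PSDensityMap:
    """Time-normalised 2D histogram of PS locations over the unit square."""

    grid: np.ndarray  # (G, G), cell [i, j] covers alpha bin i, beta bin j
    n_snapshots: int

    @property
    def total(self) -> float:
        """Mean simultaneous PS count (integral of the map)."""
        return float(self.grid.sum())


def ps_density(events, n_snapshots: int, grid: int = 32) -> PSDensityMap:
    """Histogram PS detections per UAC cell, normalised per snapshot."""
    if n_snapshots <= 0:
        raise ValueError("need at least one snapshot")
    a = np.asarray([e.alpha for e in events], dtype=float)
    b = np.asarray([e.beta for e in events], dtype=float)
    h, _, _ = np.histogram2d(a, b, bins=grid, range=((0, 1), (0, 1)))
    return PSDensityMap(h / n_snapshots, n_snapshots)


def mean_ps_count(events, n_snapshots: int) -> float:
    """Average number of simultaneous PS per analysed snapshot."""
    if n_snapshots <= 0:
        raise ValueError("need at least one snapshot")
    return len(events) / n_snapshots


def density_correlation(map1: PSDensityMap, map2: PSDensityMap) -> float:
    """Pearson correlation between two density maps over all grid cells.

    Returns NaN (with a logged warning) when either map is constant.
    """
    g1 = np.asarray(getattr(map1, "grid", map1), dtype=float).ravel()
    g2 = np.asarray(getattr(map2, "grid", map2), dtype=float).ravel()
    if g1.shape != g2.shape:
        raise ValueError("density maps have different grids")
    if np.std(g1) < 1e-300 or np.std(g2) < 1e-300:
        logger.warning("density_correlation: constant map, correlation undefined")
        return float("nan")
    return float(np.corrcoef(g1, g2)[0, 1])


def save_density_png(density: PSDensityMap, path) -> None:
    """Heatmap of a PS density map (alpha horizontal, beta vertical)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(density.grid.T, origin="lower", extent=(0, 1, 0, 1),
                   cmap="inferno", aspect="equal")
    ax.set_xlabel("alpha")
    ax.set_ylabel("beta")
    fig.colorbar(im, ax=ax, label="PS dwell / snapshot")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class AFResult:
    events: list
    density: PSDensityMap
    mean_ps: float
    termination_time: float | None
    n_snapshots: int


def af_experiment(
    system: MonodomainSystem,
    membrane,
    uac: UACField,
    spec: SpiralICSpec | None = None,
    duration: float = 10000.0,
    snapshot_dt: float = 5.0,
    tau: float = 10.0,
    grid: int = 32,
    skip: float = 50.0,
) -> AFResult:
    """Spiral ICs -> monodomain -> phase -> PS -> density map.

    PS detection runs on the endocardial layer (layer 0) of the system.
    Termination (no tissue above the activation threshold) is recorded if it
    occurs before ``duration``; the analysed window excludes the first
    ``skip`` ms while the encoded spirals form.
    """
    spec = spec or SpiralICSpec()
    mesh = system.meshes[0]
    n0 = mesh.n_vertices
    state0 = spiral_initial_state(system, membrane, spec, uac)
    times, volts, _ = run_monodomain(
        system, membrane, duration=duration, initial_state=state0,
        record_dt=snapshot_dt,
    )
    active = volts.max(axis=1) > 0.2
    termination = None
    if not active[-1]:
        quiet = np.flatnonzero(~active)
        termination = float(times[quiet[0]])
    pt, phase = compute_phase(times, volts[:, :n0], tau=tau)
    sel = pt >= skip
    if termination is not None:
        sel &= pt <= termination
    events: list[PSEvent] = []
    for t, snap in zip(pt[sel], phase[sel]):
        events.extend(detect_ps(snap, mesh, uac, time=float(t)))
    n_snap = int(sel.sum())
    dens = ps_density(events, max(n_snap, 1), grid=grid)
    return AFResult(events, dens, mean_ps_count(events, max(n_snap, 1)),
                    termination, n_snap)
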