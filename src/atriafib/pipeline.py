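"""Configuration handling and end-to-end pipeline orchestration.

One YAML config describes one reproducible run: synthetic anatomies (or
paths to meshes), UAC computation, fibre generation/mapping/averaging, LAT
pacing comparisons and the spiral-wave experiment. Every stochastic stage
records its seed; outputs are plain CSV/JSON next to a copy of the resolved
configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ep, stats
from .arrhythmia import SpiralICSpec, af_experiment, density_correlation
from .mapping import compute_uac_basis, fibre_to_angle, map_fibres
from .mesh import SurfaceMesh
from .synthetic import (
    AnatomySpec,
    FibrePatternSpec,
    default_uac_seeds,
    make_anatomy,
    make_fibre_field,
)
from .uac import UACField, build_la_bcs, build_ra_bcs, compute_uac

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "RunConfig", "load_config", "compute_chamber_uac", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key path."""


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    chamber: str = "LA"
    seed: int = 0
    n_anatomies: int = 2
    edge_length: float = 1.5
    shape_noise: float = 0.04
    fibre_kappa: float = 8.0
    noise_region: tuple | None = (0.0, 1.0, 0.42, 0.58)
    noise_region_kappa: float = 2.0
    pacing_sites: tuple = ((0.5, 0.08), (0.2, 0.45))
    sim: dict = field(default_factory=lambda: {
        "dt": 0.1, "lead_in": 200.0, "n_beats": 2, "cycle_length": 400.0,
        "record_dt": 1.0,
    })
    af: dict = field(default_factory=lambda: {
        "duration": 2000.0, "snapshot_dt": 5.0, "grid": 32, "excitability": 0.72,
    })
    out_dir: str = "atriafib_run"

    def validate(self) -> None:
        if self.chamber not in ("LA", "RA"):
            raise ConfigError(f"chamber: must be LA or RA, got {self.chamber!r}")
        if self.n_anatomies < 1:
            raise ConfigError("n_anatomies: must be >= 1")
        if self.edge_length <= 0:
            raise ConfigError("edge_length: must be positive")
        if self.fibre_kappa < 0:
            raise ConfigError("fibre_kappa: must be >= 0")
        for key in ("dt", "lead_in", "n_beats", "cycle_length", "record_dt"):
            if key not in self.sim:
                raise ConfigError(f"sim.{key}: missing")
            if self.sim[key] <= 0:
                raise ConfigError(f"sim.{key}: must be positive")
        for key in ("duration", "snapshot_dt", "grid", "excitability"):
            if key not in self.af:
                raise ConfigError(f"af.{key}: missing")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    bad = set(raw) - known
    if bad:
        raise ConfigError(f"{sorted(bad)[0]}: unknown configuration key")
    merged = RunConfig(**raw)
    if merged.noise_region is not None:
        merged.noise_region = tuple(merged.noise_region)
    merged.pacing_sites = tuple(tuple(s) for s in merged.pacing_sites)
    merged.validate()
    return merged


def compute_chamber_uac(
    mesh: SurfaceMesh, uac_seeds: dict, atlas: dict | None = None
) -> UACField:
    """Rims + landmark seeds -> boundary conditions -> coordinates."""
    if not mesh.rim_labels:
        raise ValueError("mesh has no labelled rims; run detect_rims first")
    if mesh.chamber == "LA":
        bc_a, bc_b, partition = build_la_bcs(
            mesh, mesh.rim_labels, uac_seeds["MV_septal"], atlas=atlas,
            laa_tip=mesh.landmarks.get("LAA_tip"),
        )
        return compute_uac(mesh, bc_a, bc_b, partition)
    bc_a, bc_b = build_ra_bcs(
        mesh, mesh.rim_labels,
        (uac_seeds["TV_lateral"], uac_seeds["TV_septal"]),
        atlas=atlas, raa_tip=mesh.landmarks.get("RAA_tip"),
    )
    return compute_uac(mesh, bc_a, bc_b, None)


def synthetic_case(cfg: RunConfig, index: int):
    """One synthetic anatomy with UAC and a perturbed fibre field."""
    spec = AnatomySpec(
        chamber=cfg.chamber,
        edge_length=cfg.edge_length,
        shape_noise=cfg.shape_noise if index > 0 else 0.0,
        seed=cfg.seed + 101 * index,
    )
    endo, _epi = make_anatomy(spec)
    uac = compute_chamber_uac(endo, default_uac_seeds(spec))
    pattern = FibrePatternSpec(
        angle="la_default" if cfg.chamber == "LA" else "ra_default",
        kappa=cfg.fibre_kappa,
        noise_region=cfg.noise_region,
        noise_region_kappa=cfg.noise_region_kappa,
    )
    fibres = make_fibre_field(endo, uac, pattern, seed=cfg.seed + 7 * index + 1)
    return endo, uac, fibres, pattern


def run_pipeline(cfg: RunConfig, out_dir=None) -> dict:
    """Full run: anatomies -> UAC -> mapping -> comparison -> LAT -> AF.

    Returns a summary dict (also written as JSON with CSV side files).
    """
    cfg.validate()
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(cfg)}

    cases = [synthetic_case(cfg, i) for i in range(cfg.n_anatomies)]
    ref_mesh, ref_uac, ref_fibres, _ = cases[0]

    # registration: map every fibre field to the reference anatomy
    thetas = []
    basis_ref = compute_uac_basis(ref_mesh, ref_uac)
    thetas.append(fibre_to_angle(ref_fibres, basis_ref, cfg.chamber).theta)
    for mesh_i, uac_i, fib_i, _ in cases[1:]:
        mapped, report = map_fibres(mesh_i, uac_i, fib_i, ref_mesh, ref_uac, cfg.chamber)
        summary.setdefault("mapping_reports", []).append(report)
        thetas.append(fibre_to_angle(mapped, basis_ref, cfg.chamber).theta)

    if len(thetas) >= 2:
        atlas = stats.average_fibre_field(thetas)
        summary["atlas_median_std_deg"] = float(
            np.rad2deg(np.median(atlas.std_theta[np.isfinite(atlas.std_theta)]))
        )
        e = stats.angle_difference(
            _theta_vectors(thetas[0]), _theta_vectors(atlas.mean_theta)
        )
        summary["q_pi8_vs_atlas"] = stats.q_metric(e)

    # LAT comparison between the first two fields on the reference anatomy
    mem = ep.MitchellSchaeffer()
    cond = ep.ConductivityParams()
    proto = ep.PacingProtocol(
        site_uac=cfg.pacing_sites[0],
        n_beats=int(cfg.sim["n_beats"]),
        cycle_length=cfg.sim["cycle_length"],
        lead_in=cfg.sim["lead_in"],
    )
    lat_rows = []
    if len(thetas) >= 2:
        fib_a = ref_fibres
        fib_b = _theta_field(thetas[1], basis_ref, cfg.chamber)
        for site in cfg.pacing_sites:
            p = proto.scaled(site_uac=tuple(site))
            maps = []
            for fib in (fib_a, fib_b):
                sys_ = ep.MonodomainSystem(ref_mesh, cond, fib, dt=cfg.sim["dt"])
                maps.append(ep.paced_lat(sys_, mem, ref_uac, p,
                                         record_dt=cfg.sim["record_dt"]))
            cmp_ = ep.compare_lat(maps[0], maps[1])
            lat_rows.append({
                "site": list(site),
                "median_abs_ms": cmp_["median_abs_ms"],
                "max_abs_pct": cmp_["max_abs_pct"],
            })
        summary["lat_comparisons"] = lat_rows

    # spiral-wave experiment on a bilayer of the reference anatomy
    af_mem = ep.MitchellSchaeffer(eta=cfg.af["excitability"])
    bilayer = ep.build_bilayer(ref_mesh, ref_fibres)
    sys_bi = ep.MonodomainSystem(bilayer, cond, dt=cfg.sim["dt"])
    af = af_experiment(
        sys_bi, af_mem, ref_uac,
        duration=cfg.af["duration"], snapshot_dt=cfg.af["snapshot_dt"],
        grid=int(cfg.af["grid"]),
    )
    summary["af"] = {
        "mean_ps": af.mean_ps,
        "n_events": len(af.events),
        "termination_ms": af.termination_time,
        "self_correlation": density_correlation(af.density, af.density),
    }
    np.savetxt(out / "ps_density.csv", af.density.grid, delimiter=",")
    with (out / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    return summary


def _theta_vectors(theta):
    theta = np.asarray(theta, dtype=float)
    return np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)


def _theta_field(theta, basis, chamber):
    from .mapping import angle_to_fibre

    return angle_to_fibre(np.asarray(theta, dtype=float), basis, chamber)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
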