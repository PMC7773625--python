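"""Monodomain propagation: tensors, stability, LAT extraction, bilayers."""

import numpy as np
import pytest

import atriafib as af
from atriafib import ep

from conftest import make_strip


@pytest.fixture(scope="module")
def sheet():
    return make_strip(81, 33, 20.0, 8.0)  # 0.25 mm spacing


@pytest.fixture(scope="module")
def sheet_fibres(sheet):
    return af.FibreField(np.tile([1.0, 0, 0], (sheet.n_triangles, 1)))


def plane_wave_cv(sheet, sheet_fibres, sigma_t, along="x"):
    cond = ep.ConductivityParams(sigma_t=sigma_t)
    system = ep.MonodomainSystem(sheet, cond, sheet_fibres, dt=0.05)
    mem = ep.MitchellSchaeffer()
    coord = sheet.vertices[:, 0 if along == "x" else 1]
    mask = coord < 1.0
    times, volts, _ = ep.run_monodomain(
        system, mem, duration=50.0, stim_times=[1.0], stim_mask=mask,
        stim_amplitude=1.0, record_dt=0.5,
    )
    lat = ep.extract_lat(times, volts, (0.0, 50.0))
    lo, hi = (6.0, 16.0) if along == "x" else (2.5, 6.5)
    t_lo = np.nanmedian(lat.times[np.abs(coord - lo) < 0.13])
    t_hi = np.nanmedian(lat.times[np.abs(coord - hi) < 0.13])
    return (hi - lo) / (t_hi - t_lo)


def test_conductivity_tensor_properties():
    f = np.array([1.0, 0, 0])
    n = np.array([0.0, 0, 1.0])
    t = ep.element_conductivity_tensor(f, n, 0.4, 0.1)
    w, v = np.linalg.eigh(t)
    in_plane = sorted(w[np.abs(w) > 1e-12])
    assert in_plane == pytest.approx([0.1, 0.4])
    assert np.allclose(t @ f, 0.4 * f)
    iso = ep.element_conductivity_tensor(f, n, 0.2, 0.2)
    assert np.allclose(iso, 0.2 * (np.eye(3) - np.outer(n, n)))
    with pytest.raises(ValueError):
        ep.ConductivityParams(sigma_l=0.1, sigma_t=0.4)


def test_quiescence_without_stimulus(sheet, sheet_fibres):
    system = ep.MonodomainSystem(
        sheet, ep.ConductivityParams(), sheet_fibres, dt=0.1
    )
    mem = ep.MitchellSchaeffer()
    times, volts, _ = ep.run_monodomain(system, mem, duration=200.0, record_dt=10.0)
    # normalised voltage stays at rest (0.1 mV on the 110 mV scale ~ 1e-3)
    assert np.abs(volts).max() < 1e-3


def test_cv_anisotropy_follows_square_root_law(sheet, sheet_fibres):
    cv_l = plane_wave_cv(sheet, sheet_fibres, 0.1, "x")
    cv_t = plane_wave_cv(sheet, sheet_fibres, 0.1, "y")
    assert cv_l / cv_t == pytest.approx(2.0, rel=0.05)


def test_cable_refinement_convergence():
    """Planar CV converges under refinement (Richardson ratio -> 1)."""
    cvs = []
    for h in (0.5, 0.25, 0.125):
        n = int(20.0 / h) + 1
        cable = make_strip(n, 3, 20.0, 2 * h)
        fib = af.FibreField(np.tile([1.0, 0, 0], (cable.n_triangles, 1)))
        system = ep.MonodomainSystem(cable, ep.ConductivityParams(), fib, dt=0.05)
        mem = ep.MitchellSchaeffer()
        coord = cable.vertices[:, 0]
        times, volts, _ = ep.run_monodomain(
            system, mem, duration=45.0, stim_times=[1.0],
            stim_mask=coord < 1.0, stim_amplitude=1.0, record_dt=0.25,
        )
        lat = ep.extract_lat(times, volts, (0.0, 45.0))
        t_lo = np.nanmedian(lat.times[np.abs(coord - 6) < h / 2 + 1e-9])
        t_hi = np.nanmedian(lat.times[np.abs(coord - 16) < h / 2 + 1e-9])
        cvs.append(10.0 / (t_hi - t_lo))
    assert abs(cvs[2] - cvs[1]) < abs(cvs[1] - cvs[0])
    assert cvs[2] == pytest.approx(cvs[1], rel=0.05)


def test_explicit_diffusion_cfl_guard(sheet, sheet_fibres):
    with pytest.raises(ValueError, match="CFL"):
        ep.MonodomainSystem(
            sheet, ep.ConductivityParams(), sheet_fibres, dt=0.5,
            diffusion="explicit",
        )
    # a stable explicit step is accepted
    ep.MonodomainSystem(
        sheet, ep.ConductivityParams(), sheet_fibres, dt=0.005,
        diffusion="explicit",
    )


def test_instability_aborts_with_diagnostics(sheet, sheet_fibres):
    system = ep.MonodomainSystem(sheet, ep.ConductivityParams(), sheet_fibres, dt=0.1)
    mem = ep.MitchellSchaeffer()
    with pytest.raises(FloatingPointError, match="instability"):
        ep.run_monodomain(
            system, mem, duration=20.0, stim_times=[0.0],
            stim_mask=np.ones(system.n_nodes, bool),
            stim_amplitude=1e4, record_dt=1.0,
        )


def test_extract_lat_contract(sheet, sheet_fibres):
    system = ep.MonodomainSystem(sheet, ep.ConductivityParams(), sheet_fibres, dt=0.05)
    mem = ep.MitchellSchaeffer()
    mask = sheet.vertices[:, 0] < 1.0
    times, volts, _ = ep.run_monodomain(
        system, mem, duration=50.0, stim_times=[5.0], stim_mask=mask,
        stim_amplitude=1.0, record_dt=0.5,
    )
    lat = ep.extract_lat(times, volts, (0.0, 50.0))
    assert lat.n_missing == 0
    stim_lat = np.nanmin(lat.times[mask])
    assert stim_lat == pytest.approx(5.0, abs=2.0)
    # no capture -> all missing
    quiet, vq, _ = ep.run_monodomain(system, mem, duration=20.0, record_dt=1.0)
    lat_q = ep.extract_lat(quiet, vq, (0.0, 20.0), threshold=0.5)
    assert lat_q.n_missing == system.n_nodes


def test_isotropic_disc_lat_proportional_to_distance():
    # equal conductivities: the tensor is isotropic and the fibre direction
    # is irrelevant, so the wave is circular and LAT ~ distance / CV
    square = make_strip(73, 73, 24.0, 24.0)
    iso = ep.isotropic_control(square, seed=0)
    system = ep.MonodomainSystem(
        square, ep.ConductivityParams(sigma_l=0.4, sigma_t=0.4), iso, dt=0.05
    )
    mem = ep.MitchellSchaeffer()
    centre = np.array([12.0, 12.0, 0.0])
    d = np.linalg.norm(square.vertices - centre, axis=1)
    times, volts, _ = ep.run_monodomain(
        system, mem, duration=40.0, stim_times=[1.0], stim_mask=d < 1.0,
        stim_amplitude=1.0, record_dt=0.5,
    )
    lat = ep.extract_lat(times, volts, (0.0, 40.0))
    # annulus clear of the stimulus near field and the sheet boundary
    sel = (d > 2.0) & (d < 11.0) & np.isfinite(lat.times)
    r = np.corrcoef(d[sel], lat.times[sel])[0, 1]
    assert r**2 > 0.99


def test_compare_lat_shift_and_oracle():
    a = ep.LATMap(np.array([0.0, 1, 2, 3, np.nan]))
    same = ep.compare_lat(a, a)
    assert same["median_abs_ms"] == 0.0 and same["max_abs_pct"] == 0.0
    b = ep.LATMap(a.times + 2.5)
    shifted = ep.compare_lat(a, b)
    assert shifted["median_abs_ms"] == pytest.approx(2.5)
    rng = np.random.default_rng(0)
    x = ep.LATMap(rng.uniform(0, 100, 200))
    y = ep.LATMap(rng.uniform(0, 100, 200))
    out = ep.compare_lat(x, y)
    delta = np.abs(x.times - y.times)
    assert out["median_abs_ms"] == pytest.approx(np.median(delta))
    assert out["max_abs_pct"] == pytest.approx(
        100 * delta.max() / (x.times.max() - x.times.min())
    )


def test_bilayer_construction_and_coupling_limits(la_mesh, la_fibres, la_uac):
    bil = ep.build_bilayer(la_mesh, la_fibres, coupling=0.0)
    assert bil.n_nodes == 2 * la_mesh.n_vertices
    assert np.allclose(
        np.linalg.norm(bil.epi.vertices - bil.endo.vertices, axis=1), 0.1,
        atol=0.02,
    )
    mem = ep.MitchellSchaeffer()
    proto = ep.PacingProtocol(site_uac=(0.5, 0.1), n_beats=1,
                              cycle_length=300.0, lead_in=20.0,
                              stim_amplitude=1.0)
    single = ep.MonodomainSystem(la_mesh, ep.ConductivityParams(), la_fibres, dt=0.1)
    lat_single = ep.paced_lat(single, mem, la_uac, proto, lat_threshold=0.5)
    # decoupled bilayer: endocardial LAT equals the single-surface LAT
    sys0 = ep.MonodomainSystem(bil, ep.ConductivityParams(), dt=0.1)
    lat0 = ep.paced_lat(sys0, mem, la_uac, proto, lat_threshold=0.5)
    n = la_mesh.n_vertices
    endo_lat = lat0.times[:n]
    ok = np.isfinite(endo_lat) & np.isfinite(lat_single.times)
    assert np.nanmax(np.abs(endo_lat[ok] - lat_single.times[ok])) < 1e-6
    # strong coupling with identical fibres: layers lock together
    bil_strong = ep.build_bilayer(la_mesh, la_fibres, coupling=50.0)
    sys1 = ep.MonodomainSystem(bil_strong, ep.ConductivityParams(), dt=0.1)
    lat1 = ep.paced_lat(sys1, mem, la_uac, proto)
    dd = np.abs(lat1.times[:n] - lat1.times[n:])
    assert np.nanmax(dd) < 1.0


def test_isotropic_control_field(la_mesh):
    f1 = ep.isotropic_control(la_mesh, seed=5)
    f2 = ep.isotropic_control(la_mesh, seed=5)
    assert np.array_equal(f1.vectors, f2.vectors)
    f1.validate(la_mesh)
    # angles uniform on [0, pi): KS test against the uniform law
    from scipy.stats import kstest
    from atriafib.mapping import compute_uac_basis, fibre_to_angle

    big, _ = af.make_anatomy(af.AnatomySpec(chamber="LA", edge_length=1.5, seed=2))
    rng_field = ep.isotropic_control(big, seed=9)
    n = big.triangle_normals()
    ref = np.zeros_like(n)
    ref[np.arange(len(n)), np.argmin(np.abs(n), axis=1)] = 1.0
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(n, e1)
    ang = np.mod(np.arctan2(
        np.einsum("ij,ij->i", rng_field.vectors, e2),
        np.einsum("ij,ij->i", rng_field.vectors, e1),
    ), np.pi)
    stat = kstest(ang / np.pi, "uniform")
    assert stat.pvalue > 0.01
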