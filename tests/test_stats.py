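"""Axial circular statistics and the fibre-field comparison metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import atriafib as af
from atriafib.stats import (
    RegionSpec,
    angle_class_percentages,
    angle_difference,
    average_fibre_field,
    circular_mean_std,
    q_metric,
    region_masks,
)


def brute_force_axial_mean(angles, n_grid=4000):
    """Independent oracle: grid-minimise the axial circular variance
    (mean of sin^2 of the period-pi deviation), refined in two stages."""

    def cost(candidates):
        d = angles[None, :] - candidates[:, None]
        return np.mean(np.sin(d) ** 2, axis=1)

    grid = np.linspace(0, np.pi, n_grid, endpoint=False)
    best = grid[np.argmin(cost(grid))]
    h = np.pi / n_grid
    fine = best + np.linspace(-h, h, 4001)
    return float(np.mod(fine[np.argmin(cost(fine))], np.pi))


def test_examples():
    mu, s = circular_mean_std(np.full(5, np.pi / 4))
    assert mu == pytest.approx(np.pi / 4) and s == 0.0
    mu, _ = circular_mean_std(np.array([0.1, np.pi - 0.1]))
    assert mu == pytest.approx(0.0, abs=1e-12)
    mu, s = circular_mean_std(np.array([0.0, np.pi / 2]))
    assert mu == 0.0 and s == np.inf
    with pytest.raises(ValueError):
        circular_mean_std(np.array([]))


def test_matches_scipy_circmean_circstd():
    from scipy.stats import circmean, circstd

    rng = np.random.default_rng(42)
    for _ in range(50):
        x = rng.uniform(0, np.pi, size=rng.integers(2, 30))
        mu, s = circular_mean_std(x)
        assert mu == pytest.approx(circmean(x, high=np.pi, low=0), abs=1e-9)
        assert s == pytest.approx(circstd(x, high=np.pi, low=0), abs=1e-9)


@settings(deadline=None, max_examples=60)
@given(st.lists(st.floats(0, np.pi - 1e-9), min_size=2, max_size=12))
def test_mean_agrees_with_brute_force_minimiser(angles):
    x = np.asarray(angles)
    mu, _ = circular_mean_std(x)
    c = np.mean(np.cos(2 * x))
    s = np.mean(np.sin(2 * x))
    if np.hypot(c, s) < 1e-3:
        return  # near-dispersed sets have an ill-conditioned minimiser
    bf = brute_force_axial_mean(x)
    d = abs(mu - bf)
    assert min(d, np.pi - d) < 1e-6


def test_average_field_duplicate_and_permutation(la_fibres, la_mesh, la_uac):
    from atriafib.mapping import compute_uac_basis, fibre_to_angle

    basis = compute_uac_basis(la_mesh, la_uac)
    theta = fibre_to_angle(la_fibres, basis, "LA").theta
    atlas = average_fibre_field([theta, theta])
    assert np.allclose(atlas.mean_theta, theta, atol=1e-9)
    assert np.allclose(atlas.std_theta, 0.0, atol=1e-7)
    rng = np.random.default_rng(0)
    fields = [np.mod(theta + 0.1 * rng.standard_normal(len(theta)), np.pi)
              for _ in range(4)]
    a1 = average_fibre_field(fields)
    a2 = average_fibre_field(fields[::-1])
    # identical up to float summation order
    assert np.allclose(a1.mean_theta, a2.mean_theta, atol=1e-12)
    with pytest.raises(ValueError, match="mismatch"):
        average_fibre_field([theta, theta[:-1]])


@pytest.mark.parametrize(
    "ang, expect",
    [(0.0, 0.0), (np.pi / 2, np.pi / 2), (3 * np.pi / 4, np.pi / 4)],
)
def test_angle_difference_formula(ang, expect):
    n = 5
    f1 = np.tile([1.0, 0, 0], (n, 1))
    f2 = np.tile([np.cos(ang), np.sin(ang), 0.0], (n, 1))
    e = angle_difference(f1, f2)
    assert np.allclose(e, expect, atol=1e-12)


def test_angle_difference_symmetries():
    rng = np.random.default_rng(1)
    f1 = rng.standard_normal((50, 3))
    f2 = rng.standard_normal((50, 3))
    assert np.allclose(angle_difference(f1, f2), angle_difference(f2, f1))
    assert np.allclose(angle_difference(f1, f2), angle_difference(-f1, f2))
    assert angle_difference(f1, f2).max() <= np.pi / 2 + 1e-12
    with pytest.raises(ValueError, match="zero"):
        angle_difference(np.zeros((2, 3)), np.ones((2, 3)))


def test_q_metric_threshold_cases():
    e_same = np.zeros(10)
    assert q_metric(e_same) == 1.0
    assert q_metric(np.full(10, np.pi / 6)) == 0.0
    assert q_metric(np.full(10, np.pi / 16)) == 1.0
    # monotone non-increasing in threshold
    rng = np.random.default_rng(2)
    e = rng.uniform(0, np.pi / 2, 500)
    qs = [q_metric(e, threshold=t) for t in np.linspace(0.05, 1.5, 12)]
    assert all(a <= b for a, b in zip(qs, qs[1:]))
    with pytest.raises(ValueError, match="mask"):
        q_metric(e, np.zeros(500, dtype=bool))


def test_angle_class_percentages():
    out = angle_class_percentages(np.zeros(50))
    assert out["class_0"] == 100.0 and out["class_pi/2"] == 0.0
    out = angle_class_percentages(np.full(50, np.pi / 2))
    assert out["class_pi/2"] == 100.0
    # boundary values belong to the reference-axis class
    out = angle_class_percentages(np.array([np.pi / 4, 5 * np.pi / 6]))
    assert out["class_0"] == 100.0
    # uniform angles: band fraction = (5pi/6 - pi/4) / pi
    rng = np.random.default_rng(3)
    theta = rng.uniform(0, np.pi, 1_000_000)
    out = angle_class_percentages(theta)
    expect = 100.0 * (5 * np.pi / 6 - np.pi / 4) / np.pi
    assert out["class_pi/2"] == pytest.approx(expect, abs=0.2)


def test_region_masks_partition(la_mesh, la_uac):
    spec = RegionSpec.la_default()
    masks = region_masks(la_uac, spec, la_mesh)
    assert set(masks) == {"posterior_wall", "roof", "anterior_wall", "LAA", "PV"}
    total = np.zeros(la_mesh.n_triangles, dtype=int)
    for m in masks.values():
        total += m.astype(int)
    assert (total == 1).all()  # default boxes partition the elements
    empty = RegionSpec(boxes={"nothing": (0.4, 0.4, 0.4, 0.4)})
    m = region_masks(la_uac, empty, la_mesh)["nothing"]
    assert m.sum() == 0
    with pytest.raises(ValueError, match="unit square"):
        RegionSpec(boxes={"bad": (-0.1, 0.5, 0, 1)}).validate()


def test_std_histogram_is_density():
    rng = np.random.default_rng(4)
    fields = [rng.uniform(0, np.pi, 400) for _ in range(5)]
    atlas = average_fibre_field(fields, n_hist_bins=30)
    dens, edges = atlas.std_histogram
    assert np.isclose(np.sum(dens * np.diff(edges)), 1.0, atol=1e-6)
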