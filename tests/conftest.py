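"""Shared fixtures: small analytic meshes and cached synthetic anatomies.

The synthetic LA/RA shells and their coordinate fields are expensive, so
they are built once per session at a coarse test resolution (1.5 mm edges)
and shared read-only across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import atriafib as af
from atriafib.pipeline import compute_chamber_uac
from atriafib.synthetic import default_uac_seeds


def make_strip(nx: int = 21, ny: int = 6, lx: float = 10.0, ly: float = 2.0):
    """Flat rectangular strip in the z=0 plane, consistent orientation."""
    xs = np.linspace(0, lx, nx)
    ys = np.linspace(0, ly, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)], axis=1)
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            c = i * ny + j + 1
            d = (i + 1) * ny + j + 1
            tris += [[a, b, d], [a, d, c]]
    return af.SurfaceMesh(verts, np.asarray(tris))


@pytest.fixture(scope="session")
def strip():
    return make_strip()


@pytest.fixture(scope="session")
def strip_uac(strip):
    """Exact planar coordinates on the strip (alpha = x/lx, beta = y/ly)."""
    lx = strip.vertices[:, 0].max()
    ly = strip.vertices[:, 1].max()
    return af.UACField(strip.vertices[:, 0] / lx, strip.vertices[:, 1] / ly)


@pytest.fixture(scope="session")
def la_spec():
    return af.AnatomySpec(chamber="LA", edge_length=1.5, seed=0)


@pytest.fixture(scope="session")
def la_mesh(la_spec):
    endo, _ = af.make_anatomy(la_spec)
    return endo


@pytest.fixture(scope="session")
def la_uac(la_mesh, la_spec):
    return compute_chamber_uac(la_mesh, default_uac_seeds(la_spec))


@pytest.fixture(scope="session")
def ra_spec():
    return af.AnatomySpec(chamber="RA", radii=(30.0, 26.0, 24.0), edge_length=1.5, seed=0)


@pytest.fixture(scope="session")
def ra_mesh(ra_spec):
    endo, _ = af.make_anatomy(ra_spec)
    return endo


@pytest.fixture(scope="session")
def ra_uac(ra_mesh, ra_spec):
    return compute_chamber_uac(ra_mesh, default_uac_seeds(ra_spec))


@pytest.fixture(scope="session")
def la_pattern():
    return af.FibrePatternSpec(angle="la_default", kappa=np.inf)


@pytest.fixture(scope="session")
def la_fibres(la_mesh, la_uac, la_pattern):
    return af.make_fibre_field(la_mesh, la_uac, la_pattern, seed=1)
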