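"""Circular statistics for axial (period-pi) fibre data and comparison metrics.

Fibre orientations are axial: theta and theta + pi describe the same fibre.
All statistics therefore work on the doubled angle 2*theta, where the axial
data become ordinary circular data. The circular mean is half the resultant
direction of the doubled angles; the circular standard deviation is half the
doubled-angle circular standard deviation sqrt(-2 ln R).

Comparison metrics between two fibre fields follow the acute-angle
convention: E_i = arccos(|cos| of the angle between the vectors), folded to
[0, pi/2], and Q_threshold is the fraction of elements with E_i below the
threshold (pi/8 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "circular_mean_std",
    "AtlasField",
    "average_fibre_field",
    "angle_difference",
    "q_metric",
    "angle_class_percentages",
    "RegionSpec",
    "region_masks",
    "LA_REGION_DEFAULTS",
    "RA_REGION_DEFAULTS",
]


def circular_mean_std(angles, period: float = np.pi) -> tuple[float, float]:
    """Axial circular mean and standard deviation of a nonempty angle set.

    Computed from the resultant of the doubled angles
    (``phi = angles * 2*pi/period``): ``mu = (period/2/pi) * atan2(S, C)``
    wrapped to [0, period), ``s = (period/2/pi) * sqrt(-2 ln Rbar)``. A zero
    resultant (perfectly dispersed set) returns ``mu = 0`` by convention and
    ``s = inf``.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circular_mean_std: empty input")
    scale = 2.0 * np.pi / period
    phi = angles * scale
    c = np.mean(np.cos(phi))
    s = np.mean(np.sin(phi))
    rbar = np.hypot(c, s)
    if rbar < 1e-12:
        return 0.0, float("inf")
    mu = np.mod(np.arctan2(s, c), 2.0 * np.pi) / scale
    mu = np.mod(mu, period)
    std = np.sqrt(-2.0 * np.log(rbar)) / scale
    return float(mu), float(std)


def _doubled_resultant(theta_stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column resultant of doubled angles for a (K, M) stack."""
    c = np.mean(np.cos(2 * theta_stack), axis=0)
    s = np.mean(np.sin(2 * theta_stack), axis=0)
    return c, s


@dataclass
class AtlasField:
    """Per-element circular mean angle and circular standard deviation."""

    mean_theta: np.ndarray
    std_theta: np.ndarray
    n_fields: int = 0
    std_histogram: tuple[np.ndarray, np.ndarray] | None = None


def average_fibre_field(
    angle_fields, n_hist_bins: int = 50
) -> AtlasField:
    """Element-wise circular mean/std over co-registered angle fields.

    ``angle_fields`` is a sequence of >= 2 per-element theta arrays on a
    common mesh. Besides the atlas field, a probability-density histogram of
    the standard deviation over elements is emitted (density over [0, pi/2]).
    Perfectly dispersed elements get std = inf and are excluded from the
    histogram.
    """
    arrays = [np.asarray(getattr(f, "theta", f), dtype=float) for f in angle_fields]
    if len(arrays) < 2:
        raise ValueError("need at least two fields to average")
    m = len(arrays[0])
    for a in arrays:
        if len(a) != m:
            raise ValueError("angle fields have mismatching element counts")
    stack = np.stack(arrays)
    c, s = _doubled_resultant(stack)
    rbar = np.hypot(c, s)
    mu = np.mod(np.mod(np.arctan2(s, c), 2 * np.pi) / 2.0, np.pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        std = np.where(rbar < 1e-12, np.inf, np.sqrt(-2.0 * np.log(np.minimum(rbar, 1.0))) / 2.0)
    mu = np.where(rbar < 1e-12, 0.0, mu)
    finite = np.isfinite(std)
    hist = np.histogram(std[finite], bins=n_hist_bins, range=(0, np.pi / 2), density=True)
    return AtlasField(mu, std, n_fields=len(arrays), std_histogram=hist)


def angle_difference(f1, f2) -> np.ndarray:
    """Acute angle E between two fibre fields, element-wise, in [0, pi/2].

    ``E = arccos(F1.F2 / (|F1||F2|))`` folded by ``E -> pi - E`` when above
    pi/2, making it symmetric and invariant to negating either field.
    """
    v1 = np.asarray(getattr(f1, "vectors", f1), dtype=float)
    v2 = np.asarray(getattr(f2, "vectors", f2), dtype=float)
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 < 1e-12) or np.any(n2 < 1e-12):
        raise ValueError("zero vector in fibre field")
    cosang = np.einsum("ij,ij->i", v1, v2) / (n1 * n2)
    e = np.arccos(np.clip(cosang, -1.0, 1.0))
    return np.where(e > np.pi / 2, np.pi - e, e)


def q_metric(e_field, mask=None, threshold: float = np.pi / 8) -> float:
    """Fraction of (masked) elements with angle difference strictly below
    the threshold (per-element count, area-unweighted)."""
    e = np.asarray(e_field, dtype=float)
    if mask is not None:
        mask = np.asarray(mask)
        if mask.dtype == bool:
            if not mask.any():
                raise ValueError("empty mask")
            e = e[mask]
        else:
            if len(mask) == 0:
                raise ValueError("empty mask")
            e = e[mask]
    if e.size == 0:
        raise ValueError("empty mask")
    return float(np.mean(e < threshold))


def angle_class_percentages(
    theta, mask=None, lower: float = np.pi / 4, upper: float = 5 * np.pi / 6
) -> dict[str, float]:
    """Split a theta field into the two directional classes, as percentages.

    ``class_0`` collects fibres along the chamber's reference axis
    (theta < pi/4 or theta > 5*pi/6: lateral-septal for the LA, IVC-SVC for
    the RA); ``class_pi/2`` collects the orthogonal class
    (pi/4 < theta < 5*pi/6). Boundary values count in ``class_0`` (the
    closed complement of the strict open band).
    """
    t = np.asarray(getattr(theta, "theta", theta), dtype=float)
    if mask is not None:
        mask = np.asarray(mask)
        t = t[mask]
    if t.size == 0:
        raise ValueError("empty mask")
    in_band = (t > lower) & (t < upper)
    pct_band = 100.0 * np.mean(in_band)
    return {"class_0": 100.0 - pct_band, "class_pi/2": pct_band}


# ----------------------------------------------------------------------
# named UAC regions
# ----------------------------------------------------------------------

#: Axis-aligned (alpha, beta) boxes (amin, amax, bmin, bmax). Wall regions
#: are disjoint; structure boxes (PV, LAA) are carved out of the walls.
LA_REGION_DEFAULTS = {
    "posterior_wall": (0.0, 1.0, 0.0, 0.42),
    "roof": (0.0, 1.0, 0.42, 0.58),
    "anterior_wall": (0.0, 1.0, 0.58, 1.0),
    "LAA": (0.70, 0.95, 0.68, 0.92),
    "PV": None,  # union of the four pinned PV boxes, built from the atlas table
}

RA_REGION_DEFAULTS = {
    "lateral_wall": (0.0, 0.45, 0.0, 1.0),
    "roof": (0.45, 0.62, 0.0, 1.0),
    "septal_wall": (0.62, 1.0, 0.0, 1.0),
    "RAA": (0.12, 0.38, 0.60, 0.90),
    "venae_cavae": (0.30, 0.70, 0.0, 0.08),  # plus the SVC band, see spec below
}


@dataclass
class RegionSpec:
    """Named axis-aligned boxes in the UAC unit square.

    ``boxes`` maps region name -> (amin, amax, bmin, bmax) or a list of such
    boxes (a region may be a union). ``carve`` lists structure regions whose
    boxes are removed from every wall region so the default spec partitions
    the square.
    """

    boxes: dict = field(default_factory=dict)
    carve: tuple = ()

    @classmethod
    def la_default(cls, atlas=None) -> "RegionSpec":
        from .uac import LA_ATLAS_DEFAULTS

        atlas = atlas or LA_ATLAS_DEFAULTS
        boxes = {k: v for k, v in LA_REGION_DEFAULTS.items() if v is not None}
        pv = []
        for name in ("LSPV", "LIPV", "RSPV", "RIPV"):
            (a, b), r = atlas[name]["centre"], atlas[name]["radius"]
            pad = 2.5 * max(r if r is not None else 0.045, 0.02)
            pv.append((a - pad, a + pad, b - pad, b + pad))
        boxes["PV"] = pv
        return cls(boxes=boxes, carve=("PV", "LAA"))

    @classmethod
    def ra_default(cls) -> "RegionSpec":
        boxes = dict(RA_REGION_DEFAULTS)
        boxes["venae_cavae"] = [
            (0.30, 0.70, 0.0, 0.08),
            (0.30, 0.70, 0.92, 1.0),
        ]
        return cls(boxes=boxes, carve=("venae_cavae", "RAA"))

    def validate(self) -> None:
        for name, bx in self.boxes.items():
            for box in (bx if isinstance(bx, list) else [bx]):
                amin, amax, bmin, bmax = box
                if not (0 <= amin <= amax <= 1 and 0 <= bmin <= bmax <= 1):
                    raise ValueError(f"region {name!r} box outside unit square")


def _in_boxes(uv: np.ndarray, bx) -> np.ndarray:
    # boxes are half-open on their upper edges (closed at the square border)
    # so that abutting wall regions partition the elements
    boxes = bx if isinstance(bx, list) else [bx]
    hit = np.zeros(len(uv), dtype=bool)
    for amin, amax, bmin, bmax in boxes:
        a_hi = uv[:, 0] <= amax if amax >= 1.0 else uv[:, 0] < amax
        b_hi = uv[:, 1] <= bmax if bmax >= 1.0 else uv[:, 1] < bmax
        hit |= (uv[:, 0] >= amin) & a_hi & (uv[:, 1] >= bmin) & b_hi
    return hit


def region_masks(uac, spec: RegionSpec, mesh) -> dict[str, np.ndarray]:
    """Boolean element masks per named region.

    An element belongs to a region iff its UAC centroid falls in the
    region's box; structure regions listed in ``spec.carve`` are removed
    from the wall regions, so the default specs partition the elements.
    """
    spec.validate()
    uv = uac.uv()[mesh.triangles].mean(axis=1)
    masks = {name: _in_boxes(uv, bx) for name, bx in spec.boxes.items()}
    carved = np.zeros(len(uv), dtype=bool)
    for name in spec.carve:
        carved |= masks[name]
    for name in masks:
        if name not in spec.carve:
            masks[name] &= ~carved
    return masks
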