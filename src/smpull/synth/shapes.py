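"""Ground-truth aggregate shapes with analytically known morphology.

Aggregates are modelled as star-convex "blobs": a unit circle perturbed by a
few random low-order cosine harmonics, then squeezed along one axis until the
polygon hits a requested circularity, and finally scaled uniformly to a
requested perimeter. Because the shape is stored as an explicit polygon, the
true perimeter, area and circularity are exact (up to the polygon
discretisation, kept well below 1%), and uniform sampling of binding sites
inside the shape reduces to a radial comparison in the unsqueezed frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ..errors import ValidationError

__all__ = [
    "GroundTruthAggregate",
    "polygon_perimeter",
    "polygon_area",
    "polygon_circularity",
    "aggregate_from_targets",
]

NM_PER_UM = 1000.0


def polygon_perimeter(vertices: np.ndarray) -> float:
    """Perimeter of a closed polygon given as (V, 2) vertices (last edge implied)."""
    d = np.diff(np.vstack([vertices, vertices[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polygon_area(vertices: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon.

    Vertices are centred first so the result stays accurate far from the
    origin (nm-scale shapes at mm-scale stage coordinates).
    """
    v = vertices - vertices.mean(axis=0)
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def polygon_circularity(vertices: np.ndarray) -> float:
    """4πA/P² of the polygon (1 for a disc, → 0 for elongated shapes)."""
    p = polygon_perimeter(vertices)
    return 4.0 * np.pi * polygon_area(vertices) / p**2


@dataclass(frozen=True)
class GroundTruthAggregate:
    """One simulated aggregate with exact morphology and binding-site layout.

    Coordinates are in nm within the field of view; morphology is stored in
    the physical units the measurement stage reports (µm, µm²).
    """

    centroid_nm: np.ndarray
    boundary_nm: np.ndarray  # (V, 2) closed polygon, last edge implied
    true_perimeter_um: float
    true_area_um2: float
    true_circularity: float
    n_binding_sites: int
    channel: str
    binding_sites_nm: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_binding_sites < 1:
            raise ValidationError("aggregate must carry at least one binding site")
        if not (0.0 < self.true_circularity <= 1.0 + 1e-9):
            raise ValidationError(f"circularity {self.true_circularity} outside (0, 1]")
        recomputed = polygon_circularity(self.boundary_nm)
        if abs(recomputed - self.true_circularity) > 0.01 * self.true_circularity:
            raise ValidationError("stored circularity disagrees with the boundary polygon")


def _radial_profile(theta: np.ndarray, coeffs: np.ndarray, phases: np.ndarray) -> np.ndarray:
    r = np.ones_like(theta)
    for k, (a, phi) in enumerate(zip(coeffs, phases), start=2):
        r = r + a * np.cos(k * theta + phi)
    return r


def _blob_vertices(coeffs, phases, squeeze: float, n_vertices: int) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = _radial_profile(theta, coeffs, phases)
    xy = np.column_stack([r * np.cos(theta) / squeeze, r * np.sin(theta)])
    return xy


def aggregate_from_targets(
    perimeter_um: float,
    circularity: float,
    centroid_nm,
    rng: np.random.Generator,
    *,
    channel: str = "alpha_syn",
    roughness: float = 0.06,
    n_harmonics: int = 4,
    site_spacing_nm: float = 20.0,
    n_vertices: int = 256,
    rotate: bool = True,
) -> GroundTruthAggregate:
    """Construct an aggregate hitting the requested (perimeter, circularity).

    The squeeze factor is solved by root finding on the exact polygon
    circularity, so targets are met to the discretisation tolerance. If the
    target circularity exceeds what the randomly perturbed blob can reach,
    the perturbation is dropped and a (near-)circular outline is used.
    """
    if perimeter_um <= 0:
        raise ValidationError("perimeter must be positive")
    if not (0.0 < circularity <= 1.0):
        raise ValidationError("target circularity must lie in (0, 1]")

    coeffs = roughness * rng.standard_normal(n_harmonics) / np.arange(2, n_harmonics + 2)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_harmonics)
    # keep the radial profile safely positive
    if np.abs(coeffs).sum() > 0.5:
        coeffs = coeffs * (0.5 / np.abs(coeffs).sum())

    def circ_at(s: float) -> float:
        return polygon_circularity(_blob_vertices(coeffs, phases, s, n_vertices))

    c_max = circ_at(1.0)
    if circularity >= c_max:  # blob cannot be rounder than its unsqueezed form
        coeffs = np.zeros_like(coeffs)
        c_max = circ_at(1.0)
        squeeze = 1.0
    if circularity < c_max:
        hi = 2.0
        while circ_at(hi) > circularity:
            hi *= 2.0
            if hi > 1024.0:
                raise ValidationError(f"target circularity {circularity} unreachable")
        squeeze = brentq(lambda s: circ_at(s) - circularity, 1.0, hi, xtol=1e-6)
    else:
        squeeze = 1.0

    verts = _blob_vertices(coeffs, phases, squeeze, n_vertices)
    scale_nm = perimeter_um * NM_PER_UM / polygon_perimeter(verts)

    if rotate:
        ang = rng.uniform(0.0, 2.0 * np.pi)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    else:
        rot = np.eye(2)

    centroid_nm = np.asarray(centroid_nm, dtype=float)
    boundary = verts * scale_nm @ rot.T
    boundary = boundary - boundary.mean(axis=0) + centroid_nm

    area_um2 = polygon_area(boundary) / NM_PER_UM**2
    perim_um = polygon_perimeter(boundary) / NM_PER_UM
    circ = 4.0 * np.pi * area_um2 / perim_um**2

    n_sites = max(1, int(round(area_um2 * NM_PER_UM**2 / site_spacing_nm**2)))
    sites = _sample_sites(coeffs, phases, squeeze, n_sites, rng)
    sites = sites * scale_nm @ rot.T
    offset = centroid_nm - (verts * scale_nm @ rot.T).mean(axis=0)
    sites = sites + offset

    return GroundTruthAggregate(
        centroid_nm=centroid_nm,
        boundary_nm=boundary,
        true_perimeter_um=perim_um,
        true_area_um2=area_um2,
        true_circularity=min(circ, 1.0),
        n_binding_sites=n_sites,
        channel=channel,
        binding_sites_nm=sites,
    )


def _sample_sites(coeffs, phases, squeeze, n_sites, rng) -> np.ndarray:
    """Uniform rejection sampling inside the star-convex blob (unit frame)."""
    r_max = 1.0 + np.abs(coeffs).sum()
    out = np.empty((0, 2))
    while len(out) < n_sites:
        cand = rng.uniform(-r_max, r_max, size=(max(4 * n_sites, 64), 2))
        rad = np.hypot(cand[:, 0], cand[:, 1])
        theta = np.arctan2(cand[:, 1], cand[:, 0])
        keep = rad <= _radial_profile(theta, coeffs, phases)
        out = np.vstack([out, cand[keep]])
    sites = out[:n_sites].copy()
    sites[:, 0] /= squeeze
    return sites
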