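"""Monte-Carlo ray tracing of coherent light reflected off the mirror array.

The device field integral is estimated by sampling K rays from the Gaussian
beam profile, intersecting each with the tilted mirror it strikes, and
coherently summing unit-amplitude phasors per output direction:

    E(b) = sum_k exp(i (2 pi / lambda) d(p_k) . (a + b)),

where ``d(p_k)`` is the 3-D intersection point of ray k and ``a + b`` is the
reflection path-difference vector (see :mod:`dmdsim.analytic` for the sign
convention).  The beam shape
enters only through the sampling density (each ray carries amplitude 1); rays
falling into gaps or off the array miss and contribute nothing.  Single
bounce only — shadowing and re-reflection between neighbouring tilted
mirrors are ignored.

This is the slowest but least constrained solver: arbitrary patterns are
supported, and the per-ray structure leaves hooks for future per-ray
wavelength/phase draws (partial coherence), which are not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    AnglePair,
    BeamProfile,
    DMDGeometry,
    angles_to_direction,
    mirror_normal,
    rotation_matrix,
)
from .maps import AngularGrid, FieldMap
from .patterns import TiltPattern

__all__ = ["RayHits", "default_beam", "sample_rays", "intersect_rays", "raytrace_field"]

# Neighbour search ring around the z=0 lattice cell of each ray.  At
# |gamma| = 12 deg and w = 7.56 um the in-plane footprint shift of a tilted
# mirror is below w * sin(12 deg) ~ 1.6 um < m, so one ring suffices.
_NEIGHBOUR_OFFSETS = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)]


@dataclass(frozen=True)
class RayHits:
    """Intersection result for a batch of rays (misses already dropped)."""

    mx: np.ndarray  # mirror index, int
    my: np.ndarray
    s_um: np.ndarray  # on-mirror coordinates, 0 <= s, t <= w
    t_um: np.ndarray
    point_um: np.ndarray  # (M, 3) intersection points d(p_k)
    n_rays: int  # rays traced, including misses

    @property
    def n_hits(self) -> int:
        return self.point_um.shape[0]


def default_beam(geom: DMDGeometry, waist_factor: float = 10.0) -> BeamProfile:
    """Gaussian beam centred on the array, waist ``waist_factor`` x its extent.

    The large default waist makes the illumination near-uniform across the
    array, which is what the analytic/grating solvers assume.
    """
    ex, ey = geom.extent_um
    cx, cy = geom.centre_um
    return BeamProfile(waist_um=waist_factor * max(ex, ey), center_x_um=cx, center_y_um=cy)


def _transverse_basis(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the plane perpendicular to ``a``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(a @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


def sample_rays(
    beam: BeamProfile,
    a,
    count: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Support vectors of ``count`` Gaussian-distributed incident rays.

    Each ray is the line ``f(u) = h + u a`` with support ``h`` perpendicular
    to the shared incidence direction ``a``.  Supports are drawn from an
    isotropic 2-D Gaussian (standard deviation ``waist/2`` per transverse
    axis) offset so the beam centre projects onto
    ``(center_x, center_y, 0)``.  Deterministic for a given seed.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    a = np.asarray(a, float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e1, e2 = _transverse_basis(a)
    centre = np.array([beam.center_x_um, beam.center_y_um, 0.0])
    h0 = centre - (centre @ a) * a  # transverse part of the beam-centre point
    sigma = beam.waist_um / 2.0
    g = rng.normal(0.0, sigma, size=(count, 2))
    return h0 + g[:, :1] * e1 + g[:, 1:] * e2


def intersect_rays(
    supports: np.ndarray,
    a,
    geom: DMDGeometry,
    pattern: TiltPattern,
) -> RayHits:
    """Exact line/tilted-plane intersections for a batch of rays.

    Each ray is projected to the z = 0 plane to locate its candidate lattice
    cell; the exact intersection is then solved against the tilted plane of
    that cell and its 8 neighbours, accepting candidates whose inverse-rotated
    local coordinates satisfy ``0 <= s, t <= w``.  When several candidates
    accept (possible near tilted mirror edges), the one struck first by the
    incoming wave (largest z) wins.  Rays accepted nowhere are misses.
    """
    pattern.validate_for(geom)
    a = np.asarray(a, float)
    if a[2] <= 0:
        raise ValueError("incidence direction must have z > 0")
    supports = np.atleast_2d(np.asarray(supports, float))
    n_rays = supports.shape[0]

    # projection to z = 0 locates the candidate cell
    u0 = -supports[:, 2] / a[2]
    p0 = supports + u0[:, None] * a
    ix = np.floor(p0[:, 0] / geom.pitch_um).astype(int)
    iy = np.floor(p0[:, 1] / geom.pitch_um).astype(int)

    rot = {
        0: rotation_matrix(geom.gamma_minus_deg),
        1: rotation_matrix(geom.gamma_plus_deg),
    }
    normal = {k: r[:, 2] for k, r in rot.items()}

    best_z = np.full(n_rays, -np.inf)
    best = {
        "mx": np.zeros(n_rays, int),
        "my": np.zeros(n_rays, int),
        "s": np.zeros(n_rays),
        "t": np.zeros(n_rays),
        "point": np.zeros((n_rays, 3)),
    }
    w = geom.mirror_um
    for dx, dy in _NEIGHBOUR_OFFSETS:
        mx, my = ix + dx, iy + dy
        in_grid = (mx >= 0) & (mx < geom.nx) & (my >= 0) & (my < geom.ny)
        if not in_grid.any():
            continue
        state = np.zeros(n_rays, int)
        state[in_grid] = pattern.states[my[in_grid], mx[in_grid]]
        origin = geom.pitch_um * np.stack([mx, my, np.zeros_like(mx)], axis=1)
        point = np.zeros((n_rays, 3))
        s = np.zeros(n_rays)
        t = np.zeros(n_rays)
        on_mirror = np.zeros(n_rays, bool)
        for k in (0, 1):
            sel = in_grid & (state == k)
            if not sel.any():
                continue
            nu = normal[k]
            u = ((origin[sel] - supports[sel]) @ nu) / (a @ nu)
            pt = supports[sel] + u[:, None] * a
            local = (pt - origin[sel]) @ rot[k]  # R^T . offset via right-multiplication
            s_k, t_k = local[:, 0], local[:, 1]
            ok = (s_k >= 0) & (s_k <= w) & (t_k >= 0) & (t_k <= w)
            idx = np.flatnonzero(sel)[ok]
            point[idx] = pt[ok]
            s[idx], t[idx] = s_k[ok], t_k[ok]
            on_mirror[idx] = True
        better = on_mirror & (point[:, 2] > best_z)
        best_z[better] = point[better, 2]
        for key, val in (("mx", mx), ("my", my), ("s", s), ("t", t), ("point", point)):
            best[key][better] = val[better]

    hit = np.isfinite(best_z)
    return RayHits(
        mx=best["mx"][hit],
        my=best["my"][hit],
        s_um=best["s"][hit],
        t_um=best["t"][hit],
        point_um=best["point"][hit],
        n_rays=n_rays,
    )


def raytrace_field(
    geom: DMDGeometry,
    pattern: TiltPattern,
    incidence: AnglePair | tuple[float, float],
    grid: AngularGrid,
    wavelength_um: float,
    count: int = 100_000,
    seed: int = 0,
    beam: BeamProfile | None = None,
    chunk: int = 512,
) -> FieldMap:
    """Monte-Carlo estimate of the diffracted far field.

    Sums one unit phasor per hitting ray for every output direction on
    ``grid``; fully reproducible for a given ``seed``.  Raises if no ray hits
    the device (beam misses it entirely).
    """
    if wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    beam = beam or default_beam(geom)
    phi_a, theta_a = incidence
    a = angles_to_direction(phi_a, theta_a)
    supports = sample_rays(beam, a, count, seed)
    hits = intersect_rays(supports, a, geom, pattern)
    if hits.n_hits == 0:
        raise ValueError("no ray hit the device; check beam centre/waist and geometry")

    b = grid.directions().reshape(-1, 3)
    k0 = 2.0 * np.pi / wavelength_um
    d = hits.point_um
    d_dot_a = d @ a
    field = np.zeros(b.shape[0], dtype=complex)
    for start in range(0, d.shape[0], chunk):
        dc = d[start : start + chunk]
        phase = k0 * (d_dot_a[start : start + chunk, None] + dc @ b.T)
        field += np.exp(1j * phase).sum(axis=0)

    return FieldMap(
        grid,
        field.reshape(grid.shape),
        meta={
            "approach": "raytrace",
            "wavelength_um": wavelength_um,
            "incidence_deg": (float(phi_a), float(theta_a)),
            "rays": count,
            "hits": hits.n_hits,
            "seed": seed,
            "beam": {
                "waist_um": beam.waist_um,
                "center_x_um": beam.center_x_um,
                "center_y_um": beam.center_y_um,
            },
        },
    )
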