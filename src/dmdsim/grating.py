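"""Envelope x native-grating factorization for uniformly tilted devices.

When every mirror sits in the same tilt state and the illumination is
uniform, the device field factorizes into the single-mirror *envelope* and
the *native grating* factor of the mirror lattice,

    E_DMD = E_single(a, b, gamma, w, lambda) * E_grating(a, b, m, Nx, Ny, lambda),
    I_DMD = I_envelope * I_grating,

exactly as in a Young-type multi-slit experiment.  The grating factor is a
product of two Dirichlet kernels and is evaluated in closed form, which makes
this by far the fastest full-field solver — at the price of not supporting
displayed patterns.

This module also hosts the envelope-centre (specular reflection off a tilted
mirror), native-order enumeration, and the envelope-to-brightest-order
*displacement* metric whose zeros locate blaze (Littrow) configurations.
"""

from __future__ import annotations

import numpy as np

from .analytic import single_mirror_field
from .geometry import (
    AnglePair,
    DMDGeometry,
    angles_to_direction,
    direction_to_angles,
    mirror_normal,
)
from .maps import AngularGrid, FieldMap

__all__ = [
    "OutOfHemisphereError",
    "grating_factor",
    "grating_field",
    "grating_intensity",
    "envelope_centre",
    "native_orders_near",
    "brightest_order",
    "displacement",
    "displacement_map",
]


class OutOfHemisphereError(ValueError):
    """The requested direction points into the z <= 0 half space."""


def _dirichlet(xi: np.ndarray, n: int) -> np.ndarray:
    """Closed-form lattice sum sum_{j=0}^{n-1} exp(i j xi).

    Equals ``exp(i (n-1) xi / 2) * sin(n xi / 2) / sin(xi / 2)`` with the
    removable singularity at ``xi = 2 pi p`` evaluated by its limit
    ``n cos(n xi / 2) / cos(xi / 2)`` (which is ``n`` up to sign bookkeeping).
    """
    xi = np.asarray(xi, float)
    half = xi / 2.0
    num = np.sin(n * half)
    den = np.sin(half)
    small = np.abs(den) < 1e-9
    safe_den = np.where(small, 1.0, den)
    ratio = np.where(small, n * np.cos(n * half) / np.cos(half), num / safe_den)
    return np.exp(1j * (n - 1) * half) * ratio


def grating_factor(geom: DMDGeometry, a, b, wavelength_um: float):
    """Native-grating factor: lattice sum of unit phasors over all Nx x Ny sites.

    Broadcasts over ``b`` (components along the last axis).  The modulus
    peaks at ``Nx * Ny`` exactly at the native diffraction orders
    ``(a + b) . e = p * lambda / m`` (order (0, 0) is the specular
    direction ``(-ax, -ay, az)``).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    delta = a + b
    k0m = 2.0 * np.pi * geom.pitch_um / wavelength_um
    return _dirichlet(k0m * delta[..., 0], geom.nx) * _dirichlet(
        k0m * delta[..., 1], geom.ny
    )


def grating_field(
    geom: DMDGeometry,
    incidence: AnglePair | tuple[float, float],
    grid: AngularGrid,
    wavelength_um: float,
    tilt_sign: str = "minus",
) -> FieldMap:
    """Complex far field for a uniform tilt state via the factorization."""
    phi_a, theta_a = incidence
    a = angles_to_direction(phi_a, theta_a)
    b = grid.directions()
    gamma = geom.gamma_deg(tilt_sign)
    field = single_mirror_field(a, b, gamma, geom.mirror_um, wavelength_um) * grating_factor(
        geom, a, b, wavelength_um
    )
    return FieldMap(
        grid,
        field,
        meta={
            "approach": "grating",
            "wavelength_um": wavelength_um,
            "incidence_deg": (float(phi_a), float(theta_a)),
            "tilt_sign": tilt_sign,
        },
    )


def grating_intensity(
    geom: DMDGeometry,
    incidence: AnglePair | tuple[float, float],
    grid: AngularGrid,
    wavelength_um: float,
    tilt_sign: str = "minus",
) -> np.ndarray:
    """Intensity map ``I_envelope * I_grating`` on the angular grid."""
    return grating_field(geom, incidence, grid, wavelength_um, tilt_sign).intensity


def envelope_centre(a, gamma_deg: float) -> np.ndarray:
    """Specular reflection of ``a`` off a mirror tilted by ``gamma`` (degrees).

    ``b_env = 2 (a . nu) nu - a`` with ``nu = R(gamma) z_hat``.  This is the
    centre of the single-mirror envelope.  Raises
    :class:`OutOfHemisphereError` if the reflected direction has z <= 0 (only
    checked for scalar input; vectorised callers inspect z themselves).
    """
    a = np.asarray(a, float)
    nu = mirror_normal(gamma_deg)
    b = 2.0 * (a @ nu)[..., None] * nu - a
    if b.ndim == 1 and b[2] <= 0:
        raise OutOfHemisphereError(
            f"envelope centre has z = {b[2]:.4f} <= 0 for gamma = {gamma_deg} deg"
        )
    return b


def _order_direction(a: np.ndarray, px, py, pitch_um: float, wavelength_um: float):
    """Direction of native order (px, py), or NaN where it is evanescent."""
    lam_m = wavelength_um / pitch_um
    bx = np.asarray(px) * lam_m - a[..., 0]
    by = np.asarray(py) * lam_m - a[..., 1]
    r2 = bx**2 + by**2
    valid = r2 < 1.0
    bz = np.sqrt(np.where(valid, 1.0 - r2, np.nan))
    return np.stack(np.broadcast_arrays(bx, by, bz), axis=-1)


def native_orders_near(
    a,
    geom: DMDGeometry,
    wavelength_um: float,
    window: tuple[float, float, float, float] | None = None,
) -> list[tuple[tuple[int, int], np.ndarray]]:
    """All propagating native orders, optionally restricted to an angular box.

    The 2-D grating equation ``(a + b) . e = p * lambda / m`` fixes the
    transverse components of each order; orders whose transverse components
    exceed 1 are evanescent and omitted.  ``window`` is
    ``(phi_min, phi_max, theta_min, theta_max)`` in degrees.
    """
    a = np.asarray(a, float)
    lam_m = wavelength_um / geom.pitch_um
    px_lo = int(np.ceil((a[0] - 1.0) / lam_m))
    px_hi = int(np.floor((a[0] + 1.0) / lam_m))
    py_lo = int(np.ceil((a[1] - 1.0) / lam_m))
    py_hi = int(np.floor((a[1] + 1.0) / lam_m))
    orders = []
    for px in range(px_lo, px_hi + 1):
        for py in range(py_lo, py_hi + 1):
            b = _order_direction(a, px, py, geom.pitch_um, wavelength_um)
            if not np.isfinite(b[2]) or b[2] <= 0:
                continue
            if window is not None:
                phi, theta = direction_to_angles(b)
                if not (window[0] <= phi <= window[1] and window[2] <= theta <= window[3]):
                    continue
            orders.append(((px, py), b))
    return orders


def _angle_between_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    cross = np.linalg.norm(np.cross(u, v), axis=-1)
    dot = np.einsum("...i,...i->...", u, v)
    return np.degrees(np.arctan2(cross, dot))


def _brightest_order_vec(
    a: np.ndarray,
    geom: DMDGeometry,
    wavelength_um: float,
    gamma_deg: float,
    search: int = 4,
):
    """Vectorised brightest-order search around the envelope centre.

    ``a`` has shape (..., 3).  Returns ``(b_env, b_best, px, py)`` with NaN
    where the envelope centre leaves the hemisphere or no order propagates.
    The envelope (sinc^2) decays monotonically away from its centre on the
    order-spacing scale, so the global argmax over orders lies within a few
    orders of the envelope centre; ``search`` spans the half-width of the
    candidate window in order indices.
    """
    nu = mirror_normal(gamma_deg)
    b_env = 2.0 * np.einsum("...i,i->...", a, nu)[..., None] * nu - a
    in_hemi = b_env[..., 2] > 0

    lam_m = wavelength_um / geom.pitch_um
    px0 = np.rint((a[..., 0] + b_env[..., 0]) / lam_m).astype(int)
    py0 = np.rint((a[..., 1] + b_env[..., 1]) / lam_m).astype(int)

    best_i = np.full(a.shape[:-1], -np.inf)
    best_b = np.full(a.shape, np.nan)
    best_px = np.zeros(a.shape[:-1], dtype=int)
    best_py = np.zeros(a.shape[:-1], dtype=int)
    offsets = range(-search, search + 1)
    for di in offsets:
        for dj in offsets:
            px, py = px0 + di, py0 + dj
            b = _order_direction(a, px, py, geom.pitch_um, wavelength_um)
            ok = np.isfinite(b[..., 2]) & (b[..., 2] > 0) & in_hemi
            if not ok.any():
                continue
            inten = np.where(
                ok,
                np.abs(
                    single_mirror_field(
                        a, np.nan_to_num(b), gamma_deg, geom.mirror_um, wavelength_um
                    )
                )
                ** 2,
                -np.inf,
            )
            better = inten > best_i
            best_i = np.where(better, inten, best_i)
            best_b = np.where(better[..., None], b, best_b)
            best_px = np.where(better, px, best_px)
            best_py = np.where(better, py, best_py)
    b_env = np.where(in_hemi[..., None], b_env, np.nan)
    return b_env, best_b, best_px, best_py


def brightest_order(
    incidence: AnglePair | tuple[float, float],
    geom: DMDGeometry,
    wavelength_um: float,
    tilt_sign: str = "minus",
) -> tuple[tuple[int, int], np.ndarray]:
    """Native order carrying the highest envelope intensity.

    The grating factor peaks with equal modulus ``Nx * Ny`` at every order,
    so the single-mirror envelope alone decides which order is brightest.
    """
    phi_a, theta_a = incidence
    a = angles_to_direction(phi_a, theta_a)
    gamma = geom.gamma_deg(tilt_sign)
    envelope_centre(a, gamma)  # raises OutOfHemisphereError if unphysical
    _, b_best, px, py = _brightest_order_vec(a, geom, wavelength_um, gamma)
    if not np.isfinite(b_best[2]):
        raise ValueError("no propagating native order near the envelope centre")
    return (int(px), int(py)), b_best


def displacement(
    incidence: AnglePair | tuple[float, float],
    geom: DMDGeometry,
    wavelength_um: float,
    tilt_sign: str = "minus",
) -> float:
    """Great-circle angle (degrees) between envelope centre and brightest order.

    Zero means the blaze (Littrow) condition is met: a native diffraction
    order coincides with the specular reflection off the tilted mirror facet,
    so that order carries the envelope maximum.
    """
    phi_a, theta_a = incidence
    a = angles_to_direction(phi_a, theta_a)
    gamma = geom.gamma_deg(tilt_sign)
    envelope_centre(a, gamma)
    b_env, b_best, _, _ = _brightest_order_vec(a, geom, wavelength_um, gamma)
    if not np.isfinite(b_best[2]):
        raise ValueError("no propagating native order near the envelope centre")
    return float(_angle_between_deg(b_env, b_best))


def displacement_map(
    geom: DMDGeometry,
    wavelength_um: float,
    incidence_range_deg: tuple[float, float] = (-60.0, 60.0),
    step_deg: float = 0.2,
    tilt_sign: str = "minus",
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement over a square grid of incidence angles.

    Returns ``(axis_deg, map)`` where ``map[i, j]`` is the displacement for
    incidence ``(phi_a, theta_a) = (axis[j], axis[i])``; NaN marks incidences
    whose envelope centre leaves the z > 0 hemisphere.  Near-zero bands are
    the blaze-compatible incidence sets.
    """
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    lo, hi = incidence_range_deg
    axis = np.arange(lo, hi + step_deg / 2.0, step_deg)
    phi, theta = np.meshgrid(axis, axis)
    a = angles_to_direction(phi, theta)
    gamma = geom.gamma_deg(tilt_sign)
    b_env, b_best, _, _ = _brightest_order_vec(a, geom, wavelength_um, gamma)
    disp = _angle_between_deg(b_env, b_best)
    return axis, disp
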