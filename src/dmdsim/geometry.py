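"""Device geometry and angle conventions for a digital micromirror device (DMD).

A DMD is a rectangular array of square micromirrors on a lattice with pitch
``m`` (micrometres).  Each mirror of edge length ``w <= m`` flips between two
steady tilt states ``gamma-`` / ``gamma+`` by rotating about its *diagonal*
axis ``n = (1, 1, 0)/sqrt(2)``.

Conventions used throughout the package:

* lengths in micrometres (including wavelengths inside the library; the CLI
  accepts nanometres),
* angles in degrees at every public interface, radians internally,
* mirror indices ``(mx, my)`` are 0-based with the lattice origin at the
  corner of mirror ``(0, 0)``; x right, y up, z towards the optics,
* directions of incidence ``a`` and diffraction ``b`` are unit vectors with
  ``z > 0`` (source and observer both on the reflective side), parameterised
  by the angle pair ``(phi, theta)`` via the tangent map
  ``a = az * (tan phi, tan theta, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "DIAGONAL_AXIS",
    "DMDGeometry",
    "AnglePair",
    "BeamProfile",
    "angles_to_direction",
    "direction_to_angles",
    "rotation_matrix",
    "mirror_normal",
    "mirror_surface_point",
]

#: Normalised tilt axis of every micromirror (the mirror diagonal).
DIAGONAL_AXIS = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)


@dataclass(frozen=True)
class DMDGeometry:
    """Micromirror array geometry.

    Parameters
    ----------
    pitch_um:
        Lattice constant ``m`` (centre-to-centre mirror spacing) in um.
    mirror_um:
        Mirror edge length ``w`` in um; the gap is ``g = m - w >= 0``.
    tilt_deg:
        Magnitude of the tilt angle; the two steady states are
        ``-tilt_deg`` and ``+tilt_deg``.
    nx, ny:
        Number of mirrors along x and y.

    Defaults correspond to a DLP6500-class device restricted to a 50 x 50
    sub-array: 7.56 um pitch, gap-free mirrors, +-12 degree tilt.
    """

    pitch_um: float = 7.56
    mirror_um: float = 7.56
    tilt_deg: float = 12.0
    nx: int = 50
    ny: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.mirror_um <= self.pitch_um:
            raise ValueError(
                f"need 0 < mirror_um <= pitch_um, got w={self.mirror_um}, m={self.pitch_um}"
            )
        if self.nx < 1 or self.ny < 1:
            raise ValueError("nx and ny must be >= 1")
        if not 0.0 < self.tilt_deg < 90.0:
            raise ValueError("tilt_deg must lie in (0, 90)")

    @property
    def gap_um(self) -> float:
        """Inter-mirror gap ``g = m - w`` in um."""
        return self.pitch_um - self.mirror_um

    @property
    def gamma_minus_deg(self) -> float:
        return -self.tilt_deg

    @property
    def gamma_plus_deg(self) -> float:
        return self.tilt_deg

    @property
    def extent_um(self) -> tuple[float, float]:
        """Overall footprint (x, y) of the array in um."""
        return self.nx * self.pitch_um, self.ny * self.pitch_um

    @property
    def centre_um(self) -> tuple[float, float]:
        ex, ey = self.extent_um
        return ex / 2.0, ey / 2.0

    def gamma_deg(self, tilt_sign: str) -> float:
        """Tilt angle for a uniform state, ``tilt_sign`` in {'minus', 'plus'}."""
        if tilt_sign == "minus":
            return self.gamma_minus_deg
        if tilt_sign == "plus":
            return self.gamma_plus_deg
        raise ValueError(f"tilt_sign must be 'minus' or 'plus', got {tilt_sign!r}")


class AnglePair(NamedTuple):
    """Direction expressed as the angle pair ``(phi, theta)`` in degrees."""

    phi_deg: float
    theta_deg: float

    @property
    def direction(self) -> np.ndarray:
        return angles_to_direction(self.phi_deg, self.theta_deg)


@dataclass(frozen=True)
class BeamProfile:
    """Collimated Gaussian beam projected onto the device plane.

    ``waist_um`` is the 1/e^2 intensity radius measured in the z=0 plane;
    the amplitude at in-plane radius r is ``exp(-r^2 / waist^2)``.
    """

    waist_um: float
    center_x_um: float = 0.0
    center_y_um: float = 0.0

    def __post_init__(self) -> None:
        if self.waist_um <= 0:
            raise ValueError("waist_um must be positive")

    def amplitude(self, x_um, y_um) -> np.ndarray:
        r2 = (np.asarray(x_um) - self.center_x_um) ** 2 + (
            np.asarray(y_um) - self.center_y_um
        ) ** 2
        return np.exp(-r2 / self.waist_um**2)


def angles_to_direction(phi_deg, theta_deg) -> np.ndarray:
    """Unit direction vector for the angle pair ``(phi, theta)``.

    Returns ``(z tan(phi), z tan(theta), z)`` with
    ``z = 1/sqrt(tan^2(phi) + tan^2(theta) + 1)``.  Broadcasts over array
    input; the components are stacked along the last axis.
    """
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    if np.any(np.abs(phi) >= np.pi / 2) or np.any(np.abs(theta) >= np.pi / 2):
        raise ValueError("angles must satisfy |phi| < 90 deg and |theta| < 90 deg")
    tp, tt = np.tan(phi), np.tan(theta)
    z = 1.0 / np.sqrt(tp**2 + tt**2 + 1.0)
    return np.stack(np.broadcast_arrays(z * tp, z * tt, z), axis=-1)


def direction_to_angles(v) -> np.ndarray:
    """Inverse of :func:`angles_to_direction`.

    Returns ``(phi_deg, theta_deg)`` stacked along the last axis; requires
    ``z > 0``.
    """
    v = np.asarray(v, dtype=float)
    x, y, z = v[..., 0], v[..., 1], v[..., 2]
    if np.any(z <= 0):
        raise ValueError("direction must have z > 0")
    return np.stack(
        np.broadcast_arrays(np.degrees(np.arctan2(x, z)), np.degrees(np.arctan2(y, z))),
        axis=-1,
    )


def rotation_matrix(gamma_deg: float) -> np.ndarray:
    """Proper rotation by ``gamma`` (degrees) about the mirror diagonal axis."""
    return Rotation.from_rotvec(np.deg2rad(gamma_deg) * DIAGONAL_AXIS).as_matrix()


def mirror_normal(gamma_deg: float) -> np.ndarray:
    """Unit normal of a mirror tilted by ``gamma`` (degrees): ``R(gamma) z_hat``."""
    return rotation_matrix(gamma_deg)[:, 2]


def mirror_surface_point(
    geom: DMDGeometry,
    mx: int,
    my: int,
    gamma_deg: float,
    s_um: float,
    t_um: float,
) -> np.ndarray:
    """Point on the surface of mirror ``(mx, my)`` in device coordinates (um).

    The mirror surface is the square ``(s, t, 0)``, ``0 <= s, t <= w``,
    rotated by ``gamma`` about the diagonal axis and translated to its
    lattice site: ``R(gamma) (s, t, 0) + m (mx, my, 0)``.
    """
    if not (0 <= mx < geom.nx and 0 <= my < geom.ny):
        raise ValueError(f"mirror index ({mx}, {my}) outside {geom.nx} x {geom.ny} array")
    w = geom.mirror_um
    if not (0.0 <= s_um <= w and 0.0 <= t_um <= w):
        raise ValueError(f"surface parameters must lie in [0, {w}] um")
    local = rotation_matrix(gamma_deg) @ np.array([s_um, t_um, 0.0])
    return local + geom.pitch_um * np.array([mx, my, 0.0])
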