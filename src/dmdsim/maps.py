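"""Angular output grids and far-field maps shared by all diffraction solvers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import angles_to_direction

__all__ = ["AngularGrid", "FieldMap", "pearson_correlation"]


@dataclass(frozen=True)
class AngularGrid:
    """Rectangular grid of diffraction directions ``(phi_b, theta_b)`` in degrees.

    Maps produced on the grid have shape ``(len(theta_deg), len(phi_deg))``:
    rows run over theta (y), columns over phi (x).
    """

    phi_deg: np.ndarray
    theta_deg: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi_deg", np.atleast_1d(np.asarray(self.phi_deg, float)))
        object.__setattr__(self, "theta_deg", np.atleast_1d(np.asarray(self.theta_deg, float)))
        if self.phi_deg.size == 0 or self.theta_deg.size == 0:
            raise ValueError("grid axes must be non-empty")

    @classmethod
    def linspace(
        cls,
        phi_min: float,
        phi_max: float,
        n_phi: int,
        theta_min: float | None = None,
        theta_max: float | None = None,
        n_theta: int | None = None,
    ) -> "AngularGrid":
        theta_min = phi_min if theta_min is None else theta_min
        theta_max = phi_max if theta_max is None else theta_max
        n_theta = n_phi if n_theta is None else n_theta
        return cls(
            np.linspace(phi_min, phi_max, n_phi),
            np.linspace(theta_min, theta_max, n_theta),
        )

    @classmethod
    def centered(cls, half_range_deg: float = 15.0, n: int = 301) -> "AngularGrid":
        """Symmetric grid ``[-half_range, +half_range]`` in both angles."""
        return cls.linspace(-half_range_deg, half_range_deg, n)

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta_deg.size, self.phi_deg.size

    @property
    def step_deg(self) -> tuple[float, float]:
        """(theta step, phi step); 0 for a degenerate axis."""
        dphi = float(self.phi_deg[1] - self.phi_deg[0]) if self.phi_deg.size > 1 else 0.0
        dtheta = (
            float(self.theta_deg[1] - self.theta_deg[0]) if self.theta_deg.size > 1 else 0.0
        )
        return dtheta, dphi

    def directions(self) -> np.ndarray:
        """Unit direction vectors on the grid, shape ``(n_theta, n_phi, 3)``."""
        phi, theta = np.meshgrid(self.phi_deg, self.theta_deg)
        return angles_to_direction(phi, theta)


@dataclass(frozen=True)
class FieldMap:
    """Complex far-field amplitude sampled on an :class:`AngularGrid`."""

    grid: AngularGrid
    field: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.shape(self.field) != self.grid.shape:
            raise ValueError(
                f"field shape {np.shape(self.field)} does not match grid {self.grid.shape}"
            )

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.field) ** 2

    def normalized_intensity(self) -> np.ndarray:
        inten = self.intensity
        peak = inten.max()
        return inten / peak if peak > 0 else inten

    def peaks(self, rel_threshold: float = 0.5) -> np.ndarray:
        """Local intensity maxima above ``rel_threshold * max`` as (row, col) pairs."""
        return find_peaks_2d(self.intensity, rel_threshold)


def find_peaks_2d(intensity: np.ndarray, rel_threshold: float = 0.5) -> np.ndarray:
    """(row, col) indices of local maxima above a fraction of the global max."""
    inten = np.asarray(intensity, float)
    local_max = ndimage.maximum_filter(inten, size=3, mode="nearest") == inten
    mask = local_max & (inten >= rel_threshold * inten.max())
    return np.argwhere(mask)


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two maps of identical shape."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must have the same shape")
    return float(np.corrcoef(a, b)[0, 1])
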