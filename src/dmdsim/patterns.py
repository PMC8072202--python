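"""Binary tilt-state patterns displayed on the micromirror array.

A pattern assigns every mirror one of the two steady tilt states.  The
encoding is a repo-wide convention: state ``1`` means ``gamma+``, state ``0``
means ``gamma-``.  Arrays are stored image-like with shape ``(ny, nx)`` and
index order ``states[my, mx]`` (row = y index), so ASCII/PNG pattern files map
onto them row by row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DMDGeometry

__all__ = ["TiltPattern", "make_pattern", "PATTERN_KINDS"]

PATTERN_KINDS = (
    "all_minus",
    "all_plus",
    "h_lines",
    "v_lines",
    "diagonal_lines",
    "checkerboard",
    "concentric_circles",
    "from_image",
)


@dataclass(frozen=True)
class TiltPattern:
    """Per-mirror binary tilt states, shape ``(ny, nx)``, values in {0, 1}."""

    states: np.ndarray

    def __post_init__(self) -> None:
        states = np.asarray(self.states)
        if states.ndim != 2:
            raise ValueError("states must be a 2-D array")
        if not np.isin(states, (0, 1)).all():
            raise ValueError("states must contain only 0 (gamma-) and 1 (gamma+)")
        object.__setattr__(self, "states", states.astype(np.uint8))

    @property
    def ny(self) -> int:
        return self.states.shape[0]

    @property
    def nx(self) -> int:
        return self.states.shape[1]

    def validate_for(self, geom: DMDGeometry) -> None:
        if (self.ny, self.nx) != (geom.ny, geom.nx):
            raise ValueError(
                f"pattern is {self.nx} x {self.ny} mirrors but geometry is "
                f"{geom.nx} x {geom.ny}"
            )

    def gamma_deg(self, geom: DMDGeometry) -> np.ndarray:
        """Per-mirror tilt angle in degrees (shape ``(ny, nx)``)."""
        self.validate_for(geom)
        return np.where(self.states == 1, geom.gamma_plus_deg, geom.gamma_minus_deg)

    @classmethod
    def uniform(cls, geom: DMDGeometry, tilt_sign: str) -> "TiltPattern":
        value = 1 if tilt_sign == "plus" else 0
        geom.gamma_deg(tilt_sign)  # validates tilt_sign
        return cls(np.full((geom.ny, geom.nx), value, dtype=np.uint8))


def make_pattern(
    kind: str,
    nx: int,
    ny: int,
    *,
    period: int | None = None,
    duty: float = 0.5,
    image: np.ndarray | None = None,
) -> TiltPattern:
    """Generate a binary tilt pattern.

    Parameters
    ----------
    kind:
        One of ``all_minus``, ``all_plus``, ``h_lines``, ``v_lines``,
        ``diagonal_lines``, ``checkerboard``, ``concentric_circles``,
        ``from_image``.
    period:
        Period in mirrors for the periodic kinds (>= 2; for ``checkerboard``
        the tile edge, >= 1).
    duty:
        Duty cycle of the line kinds: rows/columns ``r`` with
        ``(r mod period) < duty * period`` are set to state 1.
    image:
        Grayscale raster for ``from_image``; thresholded at 50% of its
        maximum.  Must already have shape ``(ny, nx)``.
    """
    if kind not in PATTERN_KINDS:
        raise ValueError(f"unknown pattern kind {kind!r}; choose from {PATTERN_KINDS}")
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")

    if kind == "all_minus":
        return TiltPattern(np.zeros((ny, nx), dtype=np.uint8))
    if kind == "all_plus":
        return TiltPattern(np.ones((ny, nx), dtype=np.uint8))

    if kind == "from_image":
        if image is None:
            raise ValueError("from_image requires the `image` argument")
        img = np.asarray(image, dtype=float)
        if img.shape != (ny, nx):
            raise ValueError(f"image shape {img.shape} does not match (ny, nx)=({ny}, {nx})")
        peak = img.max()
        if peak <= 0:
            return TiltPattern(np.zeros((ny, nx), dtype=np.uint8))
        return TiltPattern((img >= 0.5 * peak).astype(np.uint8))

    if period is None:
        raise ValueError(f"pattern kind {kind!r} requires a period")
    min_period = 1 if kind == "checkerboard" else 2
    if period < min_period:
        raise ValueError(f"period must be >= {min_period} for kind {kind!r}")

    rows = np.arange(ny)[:, None]
    cols = np.arange(nx)[None, :]

    if kind == "h_lines":
        states = ((rows % period) < duty * period) & np.ones_like(cols, dtype=bool)
    elif kind == "v_lines":
        states = ((cols % period) < duty * period) & np.ones_like(rows, dtype=bool)
    elif kind == "diagonal_lines":
        states = ((rows + cols) % period) < duty * period
    elif kind == "checkerboard":
        states = ((rows // period) + (cols // period)) % 2 == 0
    else:  # concentric_circles
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        r = np.hypot(rows - cy, cols - cx)
        states = (r // period) % 2 == 0
    return TiltPattern(states.astype(np.uint8))
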