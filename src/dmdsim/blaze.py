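"""Diagonal blaze-condition analysis and multicolour wavelength planning.

For a device mounted rotated by 45 degrees, incidence restricted to the
plane through the array diagonal ``k = (1, -1, 0)/sqrt(2)`` (perpendicular to
the mirror tilt axes) reduces the geometry to one dimension.  The incidence
angle pair ``(phi, -phi)`` maps to a single diagonal angle

    alpha = arctan(sqrt(2) * tan(phi)),

and the mirror lattice projected onto ``k`` has the diagonal lattice
constant ``m' = m / sqrt(2)``.  Constructive interference along the diagonal
requires ``n * lambda = m' (sin(alpha) + sin(beta))`` with integer order
``n``; taking ``beta = -alpha + 2*gamma`` (the envelope centre, i.e. specular
reflection off a tilted facet) gives the real-valued envelope order

    n(alpha, gamma, lambda) = (m' / lambda) (sin(alpha) + sin(-alpha + 2*gamma)),

and the blaze condition holds exactly when n is an integer.  The scalar
metric ``v = |sin(n pi)|`` is zero precisely on blaze configurations and is
symmetric in the sign of the order deviation.

Multicolour planning: two wavelengths share one incidence and tilt state when
``n1 * lambda1 = n2 * lambda2``; a third colour on the opposite tilt state
arrives at ``alpha3 = -beta + 2*gamma_plus`` and must satisfy
``lambda3 = (m'/n3)(sin(alpha3) + sin(beta))``.  With the 7.56 um /
+-12 degree device this yields the (488, 650.67, 553.9) nm design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiagonalConfig",
    "BlazeSolution",
    "WavelengthTriple",
    "diagonal_angle",
    "diagonal_angle_inverse",
    "blaze_order_real",
    "blaze_metric",
    "solve_blaze_incidence",
    "second_wavelength",
    "third_wavelength",
    "solve_triple",
    "diagonal_scan",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiagonalConfig:
    """Device parameters entering the diagonal (45-degree-mounted) analysis."""

    pitch_um: float = 7.56
    gamma_minus_deg: float = -12.0
    gamma_plus_deg: float = 12.0

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        for g in (self.gamma_minus_deg, self.gamma_plus_deg):
            if not abs(g) < 90:
                raise ValueError("|gamma| must be < 90 deg")

    @property
    def m_prime_um(self) -> float:
        """Diagonal lattice constant ``m' = m / sqrt(2)`` in um."""
        return self.pitch_um / np.sqrt(2.0)


@dataclass(frozen=True)
class BlazeSolution:
    """One blaze configuration: integer order and its angle pair."""

    order_n: int
    alpha_deg: float
    beta_deg: float
    wavelength_um: float
    gamma_deg: float
    v: float

    @property
    def beyond_90deg(self) -> bool:
        """True when |beta| > 90 deg — impractical for real optical layouts."""
        return abs(self.beta_deg) > 90.0


@dataclass(frozen=True)
class WavelengthTriple:
    """Three-colour design sharing one device: two colours on gamma-, one on gamma+."""

    lambda1_um: float
    lambda2_um: float
    lambda3_um: float
    alpha12_deg: float
    alpha3_deg: float
    beta_deg: float
    n1: int
    n2: int
    n3: int
    gamma12_deg: float
    gamma3_deg: float


def diagonal_angle(phi_deg):
    """Diagonal in-plane angle alpha for the anti-diagonal incidence (phi, -phi).

    ``alpha = arctan(sqrt(2) * tan(phi))``, degrees in and out; strictly
    monotone on (-90, 90).
    """
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    if np.any(np.abs(phi) >= np.pi / 2):
        raise ValueError("|phi| must be < 90 deg")
    return np.degrees(np.arctan(np.sqrt(2.0) * np.tan(phi)))


def diagonal_angle_inverse(alpha_deg):
    """Inverse of :func:`diagonal_angle`: ``phi = arctan(tan(alpha)/sqrt(2))``."""
    alpha = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    if np.any(np.abs(alpha) >= np.pi / 2):
        raise ValueError("|alpha| must be < 90 deg")
    return np.degrees(np.arctan(np.tan(alpha) / np.sqrt(2.0)))


def blaze_order_real(alpha_deg, gamma_deg, wavelength_um, cfg: DiagonalConfig | None = None):
    """Real-valued diffraction order of the envelope centre.

    ``n = (m'/lambda)(sin(alpha) + sin(-alpha + 2*gamma))`` with
    ``beta = -alpha + 2*gamma``; integer n means the blaze condition holds.
    """
    cfg = cfg or DiagonalConfig()
    if np.any(np.asarray(wavelength_um) <= 0):
        raise ValueError("wavelength must be positive")
    alpha = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    gamma = np.deg2rad(gamma_deg)
    return (cfg.m_prime_um / np.asarray(wavelength_um)) * (
        np.sin(alpha) + np.sin(-alpha + 2.0 * gamma)
    )


def blaze_metric(alpha_deg, gamma_deg, wavelength_um, cfg: DiagonalConfig | None = None):
    """Blaze metric ``v = |sin(n pi)|`` in [0, 1]; 0 exactly on blaze loci."""
    return np.abs(np.sin(np.pi * blaze_order_real(alpha_deg, gamma_deg, wavelength_um, cfg)))


def solve_blaze_incidence(
    order_n: int,
    gamma_deg: float,
    wavelength_um: float,
    cfg: DiagonalConfig | None = None,
) -> list[BlazeSolution]:
    """Diagonal incidence angles fulfilling the blaze condition for one order.

    Uses ``sin(alpha) + sin(2*gamma - alpha) = 2 sin(gamma) cos(alpha - gamma)``
    to solve Eq. ``n lambda = m'(sin alpha + sin beta)`` in closed form:
    ``alpha = gamma +- arccos(n lambda / (2 m' sin gamma))``.  Both branches
    are returned (they are exchanged under ``alpha <-> beta``); an empty list
    means the order is unreachable at this wavelength and tilt.
    """
    cfg = cfg or DiagonalConfig()
    if wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    gamma = np.deg2rad(gamma_deg)
    denom = 2.0 * cfg.m_prime_um * np.sin(gamma)
    if denom == 0.0:
        logger.info("gamma = 0: only order n = 0 is reachable")
        ratio = np.inf if order_n != 0 else 0.0
    else:
        ratio = order_n * wavelength_um / denom
    if abs(ratio) > 1.0:
        logger.info(
            "no blaze solution: |n lambda| = %.4g um exceeds 2 m' |sin gamma| = %.4g um",
            abs(order_n * wavelength_um),
            abs(denom),
        )
        return []
    spread = np.degrees(np.arccos(ratio))
    alphas = [gamma_deg - spread, gamma_deg + spread] if spread > 0 else [gamma_deg]
    solutions = []
    for alpha in alphas:
        beta = -alpha + 2.0 * gamma_deg
        solutions.append(
            BlazeSolution(
                order_n=order_n,
                alpha_deg=float(alpha),
                beta_deg=float(beta),
                wavelength_um=wavelength_um,
                gamma_deg=gamma_deg,
                v=float(blaze_metric(alpha, gamma_deg, wavelength_um, cfg)),
            )
        )
    return solutions


def second_wavelength(lambda1_um: float, n1: int, n2: int) -> float:
    """Second wavelength sharing incidence and tilt state with the first.

    From ``n1 lambda1 = n2 lambda2``: ``lambda2 = (n1/n2) lambda1``.
    """
    if n2 == 0:
        raise ValueError("n2 must be non-zero")
    lam2 = (n1 / n2) * lambda1_um
    if lam2 <= 0:
        raise ValueError(f"orders {n1}, {n2} give unphysical lambda2 = {lam2:.4g} um")
    return lam2


def third_wavelength(
    beta_deg: float,
    gamma_plus_deg: float,
    n3: int,
    cfg: DiagonalConfig | None = None,
) -> tuple[float, float]:
    """Third colour on the opposite tilt state, sharing the diffraction axis.

    The shared outgoing axis fixes ``alpha3 = -beta + 2*gamma_plus`` and the
    blaze condition then pins ``lambda3 = (m'/n3)(sin(alpha3) + sin(beta))``.
    Returns ``(alpha3_deg, lambda3_um)``.
    """
    cfg = cfg or DiagonalConfig()
    if n3 == 0:
        raise ValueError("n3 must be non-zero")
    alpha3 = -beta_deg + 2.0 * gamma_plus_deg
    lam3 = (cfg.m_prime_um / n3) * (
        np.sin(np.deg2rad(alpha3)) + np.sin(np.deg2rad(beta_deg))
    )
    if lam3 <= 0:
        raise ValueError(
            f"unphysical lambda3 = {lam3:.4g} um for beta={beta_deg}, "
            f"gamma+={gamma_plus_deg}, n3={n3}"
        )
    return float(alpha3), float(lam3)


def solve_triple(
    lambda1_um: float,
    n1: int,
    n2: int,
    n3: int,
    cfg: DiagonalConfig | None = None,
    branch: str = "negative",
) -> WavelengthTriple:
    """Full three-colour plan from one seed wavelength and three orders.

    Colours 1 and 2 share incidence ``alpha12`` and tilt state ``gamma-``;
    colour 3 uses ``gamma+`` and the same outgoing axis ``beta``.  ``branch``
    selects which of the two incidence branches to adopt ("negative" picks
    the solution with ``alpha < gamma``, matching a steep incidence layout).
    """
    cfg = cfg or DiagonalConfig()
    lam2 = second_wavelength(lambda1_um, n1, n2)
    sols = solve_blaze_incidence(n1, cfg.gamma_minus_deg, lambda1_um, cfg)
    if not sols:
        raise ValueError(f"order {n1} unreachable at lambda1 = {lambda1_um} um")
    sols = sorted(sols, key=lambda s: s.alpha_deg)
    sol = sols[0] if branch == "negative" else sols[-1]
    alpha3, lam3 = third_wavelength(sol.beta_deg, cfg.gamma_plus_deg, n3, cfg)
    return WavelengthTriple(
        lambda1_um=lambda1_um,
        lambda2_um=lam2,
        lambda3_um=lam3,
        alpha12_deg=sol.alpha_deg,
        alpha3_deg=alpha3,
        beta_deg=sol.beta_deg,
        n1=n1,
        n2=n2,
        n3=n3,
        gamma12_deg=cfg.gamma_minus_deg,
        gamma3_deg=cfg.gamma_plus_deg,
    )


def diagonal_scan(
    wavelengths_um: np.ndarray,
    alphas_deg: np.ndarray,
    cfg: DiagonalConfig | None = None,
    gamma_deg: float | None = None,
) -> np.ndarray:
    """Blaze metric v on a (wavelength, alpha) grid.

    Returns an array of shape ``(len(wavelengths), len(alphas))``; dark
    (near-zero) curves trace the blaze loci, one per integer order.
    """
    cfg = cfg or DiagonalConfig()
    gamma = cfg.gamma_minus_deg if gamma_deg is None else gamma_deg
    lam = np.asarray(wavelengths_um, dtype=float)[:, None]
    alpha = np.asarray(alphas_deg, dtype=float)[None, :]
    return blaze_metric(alpha, gamma, lam, cfg)
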