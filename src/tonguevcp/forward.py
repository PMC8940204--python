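"""Tetrapolar transfer impedance on a homogeneous anisotropic half-space.

The tongue is modelled as a semi-infinite homogeneous medium with uniaxial
anisotropy: complex conductivity sigma*_L along the myofiber axis and
sigma*_T across it, with

    sigma*_axis(omega) = sigma_axis + j * omega * eps0 * eps_r_axis.

For a point current source of 1 A on the surface, the surface potential at
in-plane offset (dx, dy) from the source (fiber axis along x) is

    phi(dx, dy) = 1 / (2 * pi * sqrt(sigma*_T * (sigma*_T dx^2 + sigma*_L dy^2)))

obtained from the isotropic half-space Green's function by the standard
coordinate-scaling transform.  Superposing the source (+I at A) and the
sink (−I at B) and differencing the two sense electrodes gives the transfer
impedance.  For a collinear array at angle theta from the fiber axis this
reduces to Z = k / sigma*_app(theta) with the geometric factor k and the
apparent conductivity

    sigma*_app(theta) = sqrt(sigma*_T (sigma*_T cos^2 theta + sigma*_L sin^2 theta)),

which exhibits the classical "paradox of anisotropy": an array aligned with
the fibers (theta = 0) measures the transverse conductivity.

Quasi-static approximation throughout; magnetic and propagation effects are
neglected, appropriate for the kHz range and centimetre geometry.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

from .geometry import EPSILON_0, TetrapolarConfig

__all__ = [
    "AnisotropicMedium",
    "complex_conductivities",
    "point_source_kernel",
    "transfer_impedance",
    "transfer_impedance_complex",
    "geometric_factor",
    "apparent_conductivity_closed_form",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class AnisotropicMedium:
    """Non-dispersive uniaxially anisotropic tissue.

    Parameters
    ----------
    sigma_L, sigma_T : float
        Conductivity along / across the fiber axis, S/m; must be positive.
    eps_rL, eps_rT : float
        Relative permittivity along / across the fiber axis, dimensionless.
    fiber_angle_deg : float
        Angle of the fiber axis from the array's 0° (sagittal) axis.
    """

    sigma_L: float
    sigma_T: float
    eps_rL: float = 0.0
    eps_rT: float = 0.0
    fiber_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_L <= 0 or self.sigma_T <= 0:
            raise ValueError("conductivities must be positive")
        if self.eps_rL < 0 or self.eps_rT < 0:
            raise ValueError("relative permittivities must be non-negative")


def complex_conductivities(
    medium: AnisotropicMedium, frequency_hz: float
) -> tuple[complex, complex]:
    """Per-axis complex conductivities sigma + j*omega*eps0*eps_r at one frequency."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    omega = _TWO_PI * frequency_hz
    s_l = medium.sigma_L + 1j * omega * EPSILON_0 * medium.eps_rL
    s_t = medium.sigma_T + 1j * omega * EPSILON_0 * medium.eps_rT
    return s_l, s_t


def _aniso_sqrt(arg: complex) -> complex:
    # Physically admissible media have Re(sigma*) > 0, so each factor's
    # argument lies in (-pi/2, pi/2) and the product's in (-pi, pi): the
    # principal branch cut is never crossed.  Guard anyway.
    if arg == 0:
        raise ValueError("degenerate (zero) conductivity product")
    root = cmath.sqrt(arg)
    if root.real < 0:
        raise ValueError("complex conductivity outside the physical half-plane")
    return root


def point_source_kernel(
    dx: float, dy: float, sigma_star_L: complex, sigma_star_T: complex
) -> complex:
    """Surface potential per unit current at offset (dx, dy), fiber axis along x.

    Returns 1 / (2*pi*sqrt(sigma*_T * (sigma*_T dx^2 + sigma*_L dy^2))), ohms
    (potential in volts for a 1 A point source).
    """
    if dx == 0.0 and dy == 0.0:
        raise ValueError("observation point coincides with the source")
    f = _aniso_sqrt(sigma_star_T * (sigma_star_T * dx * dx + sigma_star_L * dy * dy))
    return 1.0 / (_TWO_PI * f)


def transfer_impedance_complex(
    config: TetrapolarConfig,
    sigma_star_L: complex,
    sigma_star_T: complex,
    fiber_angle_deg: float = 0.0,
) -> complex:
    """Transfer impedance for given per-axis complex conductivities.

    Electrode coordinates are rotated by −fiber_angle so the kernel's x-axis
    coincides with the fiber axis, then the four source/sense kernel terms
    are superposed: Z = phi(A→M) − phi(A→N) − phi(B→M) + phi(B→N).
    """
    a = config.A.rotated(-fiber_angle_deg)
    b = config.B.rotated(-fiber_angle_deg)
    m = config.M.rotated(-fiber_angle_deg)
    n = config.N.rotated(-fiber_angle_deg)

    def k(p, q):
        return point_source_kernel(q.x - p.x, q.y - p.y, sigma_star_L, sigma_star_T)

    return k(a, m) - k(a, n) - k(b, m) + k(b, n)


def transfer_impedance(
    config: TetrapolarConfig, medium: AnisotropicMedium, frequency_hz: float
) -> complex:
    """Complex transfer impedance (ohms) of one tetrapolar configuration."""
    s_l, s_t = complex_conductivities(medium, frequency_hz)
    return transfer_impedance_complex(config, s_l, s_t, medium.fiber_angle_deg)


def geometric_factor(config: TetrapolarConfig) -> float:
    """Cell constant k (1/m) such that Z = k / sigma on an isotropic half-space.

    k = (1/2pi) (1/|AM| − 1/|AN| − 1/|BM| + 1/|BN|).
    """
    am = config.A.distance_to(config.M)
    an = config.A.distance_to(config.N)
    bm = config.B.distance_to(config.M)
    bn = config.B.distance_to(config.N)
    if min(am, an, bm, bn) == 0.0:
        raise ValueError("degenerate configuration: coincident electrodes")
    return (1.0 / am - 1.0 / an - 1.0 / bm + 1.0 / bn) / _TWO_PI


def apparent_conductivity_closed_form(
    theta_deg: float, sigma_star_L: complex, sigma_star_T: complex
) -> complex:
    """Apparent complex conductivity seen by a collinear array at angle theta.

    sigma*_app(theta) = sqrt(sigma*_T (sigma*_T cos^2 + sigma*_L sin^2)),
    principal branch; for any collinear tetrapolar configuration at this
    angle from the fiber axis, Z = geometric_factor / sigma*_app.
    """
    t = math.radians(theta_deg)
    c2, s2 = math.cos(t) ** 2, math.sin(t) ** 2
    return _aniso_sqrt(sigma_star_T * (sigma_star_T * c2 + sigma_star_L * s2))
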