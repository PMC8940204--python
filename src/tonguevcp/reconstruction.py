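"""From calibrated directional impedance spectra to anisotropic tissue VCP.

Two stages:

1. Apparent VCP.  Each calibrated transfer impedance z at a direction/
   frequency cell is converted through the isotropic cell constant k of the
   matching tetrapolar configuration: sigma*_app = k / z, with
   sigma_app = Re(sigma*_app) and eps_r_app = Im(sigma*_app) / (omega eps0).
   These are the direction-resolved apparent conductivity and relative
   permittivity spectra the device reports.

2. Anisotropic VCP.  Per frequency, the angular model
   sigma*_app(theta) = sqrt(sigma*_T (sigma*_T cos^2 + sigma*_L sin^2)) is
   inverted for the longitudinal/transverse complex conductivities.  With
   the 0° and 90° directions this inversion is closed-form
   (sigma*_T = sigma*_app(0°), sigma*_L = sigma*_app(90°)^2 / sigma*_T);
   with all measured directions it is a nonlinear least-squares fit in
   log-parameterized positive unknowns, initialized from the closed form,
   with relative complex residuals so every direction weighs comparably.
   By default the permittivity is tied across axes (eps_rL = eps_rT),
   reflecting the angular symmetry of permittivity observed in vivo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares as _scipy_least_squares

from .forward import apparent_conductivity_closed_form, geometric_factor
from .geometry import (
    EPSILON_0,
    ElectrodeArray,
    FrequencySweep,
    MeasurementRecord,
    MeasurementSession,
    validate_session,
)

__all__ = [
    "ApparentVCP",
    "AnisotropicVCP",
    "VCPSpectrum",
    "apparent_vcp",
    "closed_form_reconstruct",
    "least_squares_reconstruct",
    "reconstruct_session",
]

# floors for the log parameterization; far below any physiological value
_SIGMA_FLOOR = 1e-9
_EPSR_FLOOR = 1e-9


@dataclass
class ApparentVCP:
    """Direction- and frequency-resolved apparent conductivity/permittivity."""

    entries: dict[tuple[float, float], tuple[float, float]] = field(default_factory=dict)

    def add(self, direction_deg: float, frequency_hz: float,
            sigma_app: float, eps_r_app: float) -> None:
        self.entries[(float(direction_deg), float(frequency_hz))] = (sigma_app, eps_r_app)

    def at(self, direction_deg: float, frequency_hz: float) -> tuple[float, float]:
        return self.entries[(float(direction_deg), float(frequency_hz))]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "direction_deg": d,
                "frequency_hz": f,
                "sigma_app_S_per_m": s,
                "eps_r_app": e,
            }
            for (d, f), (s, e) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnisotropicVCP:
    """Reconstructed tissue properties at one frequency."""

    frequency_hz: float
    sigma_L: float
    sigma_T: float
    eps_rL: float
    eps_rT: float
    fit_residual: float
    method: str  # "closed_form" or "least_squares"
    converged: bool = True

    @property
    def eps_r(self) -> float:
        """Permittivity when tied across axes (mean otherwise)."""
        return 0.5 * (self.eps_rL + self.eps_rT)


@dataclass
class VCPSpectrum:
    """Reconstructed anisotropic VCP across the frequency sweep."""

    fits: list[AnisotropicVCP] = field(default_factory=list)

    def at(self, frequency_hz: float) -> AnisotropicVCP:
        for fit in self.fits:
            if math.isclose(fit.frequency_hz, frequency_hz, rel_tol=1e-12):
                return fit
        raise KeyError(f"no fit at {frequency_hz} Hz")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "frequency_hz": f.frequency_hz,
                "sigma_L_S_per_m": f.sigma_L,
                "sigma_T_S_per_m": f.sigma_T,
                "eps_rL": f.eps_rL,
                "eps_rT": f.eps_rT,
                "residual": f.fit_residual,
                "method": f.method,
                "converged": f.converged,
            }
            for f in sorted(self.fits, key=lambda x: x.frequency_hz)
        ]
        return pd.DataFrame(rows)


def apparent_vcp(record: MeasurementRecord, k: float) -> tuple[float, float]:
    """Apparent (conductivity S/m, relative permittivity) from one record.

    sigma*_app = k / z; the real part is the apparent conductivity and the
    imaginary part, divided by omega*eps0, the apparent relative
    permittivity.
    """
    if k <= 0:
        raise ValueError("cell constant must be positive")
    if record.z == 0:
        raise ValueError("zero impedance")
    sigma_star = k / record.z
    omega = 2.0 * math.pi * record.frequency_hz
    return sigma_star.real, sigma_star.imag / (omega * EPSILON_0)


def closed_form_reconstruct(
    sigma_star_app_0: complex, sigma_star_app_90: complex
) -> tuple[complex, complex]:
    """Exact inversion from the 0° and 90° apparent conductivities.

    Returns (sigma*_T, sigma*_L).  The 0° (fiber-aligned) measurement gives
    the transverse value directly — the paradox of anisotropy — and the 90°
    value then yields sigma*_L = sigma*_app(90°)^2 / sigma*_T.
    """
    if sigma_star_app_0 == 0:
        raise ValueError("zero apparent conductivity at 0°")
    sigma_t = sigma_star_app_0
    sigma_l = sigma_star_app_90**2 / sigma_t
    return sigma_t, sigma_l


def _split_sigma_star(sigma_star: complex, omega: float) -> tuple[float, float]:
    return sigma_star.real, sigma_star.imag / (omega * EPSILON_0)


def least_squares_reconstruct(
    apparent: dict[float, complex],
    frequency_hz: float,
    isotropic_permittivity: bool = True,
    fiber_angle_deg: float = 0.0,
    max_iter: int = 500,
) -> AnisotropicVCP:
    """Fit (sigma_L, sigma_T, eps_r[, eps_rL/eps_rT]) to directional data.

    Parameters
    ----------
    apparent : dict
        Measured complex apparent conductivity per direction (degrees), at
        one frequency.
    isotropic_permittivity : bool
        Tie eps_rL = eps_rT (default), consistent with the observed angular
        symmetry of tissue permittivity; set False to fit both axes.

    Minimizes sum_theta |model(theta) − meas(theta)|^2 / |meas(theta)|^2
    over log-parameterized positive unknowns (positivity by construction,
    no constrained solver needed), initialized from the 0°/90° closed form
    when those directions are present, else from the isotropic mean.

    Raises
    ------
    ValueError
        If fewer directions than needed to determine the free parameters.
    RuntimeError
        If the solver exhausts ``max_iter`` without converging.
    """
    directions = sorted(apparent)
    n_params = 3 if isotropic_permittivity else 4
    # each direction contributes two real equations
    if 2 * len(directions) < n_params:
        raise ValueError(
            f"{len(directions)} directions cannot determine {n_params} parameters"
        )
    omega = 2.0 * math.pi * frequency_hz
    meas = np.array([apparent[d] for d in directions], dtype=complex)
    weights = 1.0 / np.abs(meas)
    thetas = np.radians(np.asarray(directions, dtype=float) - fiber_angle_deg)
    c2, s2 = np.cos(thetas) ** 2, np.sin(thetas) ** 2

    # initialization
    def _find(angle):
        for d in directions:
            if math.isclose(d - fiber_angle_deg, angle, abs_tol=1e-9):
                return apparent[d]
        return None

    app_0, app_90 = _find(0.0), _find(90.0)
    if app_0 is not None and app_90 is not None:
        s_t0, s_l0 = closed_form_reconstruct(app_0, app_90)
    else:
        iso = complex(np.mean(meas))
        s_t0 = s_l0 = iso
    sig_t0, eps_t0 = _split_sigma_star(s_t0, omega)
    sig_l0, eps_l0 = _split_sigma_star(s_l0, omega)
    sig_t0 = max(sig_t0, _SIGMA_FLOOR)
    sig_l0 = max(sig_l0, _SIGMA_FLOOR)
    eps_t0 = max(eps_t0, _EPSR_FLOOR)
    eps_l0 = max(eps_l0, _EPSR_FLOOR)

    if isotropic_permittivity:
        x0 = np.log([sig_l0, sig_t0, 0.5 * (eps_l0 + eps_t0)])
    else:
        x0 = np.log([sig_l0, sig_t0, eps_l0, eps_t0])

    def unpack(x):
        if isotropic_permittivity:
            sig_l, sig_t, eps = np.exp(x)
            return sig_l, sig_t, eps, eps
        sig_l, sig_t, eps_l, eps_t = np.exp(x)
        return sig_l, sig_t, eps_l, eps_t

    def residuals(x):
        sig_l, sig_t, eps_l, eps_t = unpack(x)
        s_l = sig_l + 1j * omega * EPSILON_0 * eps_l
        s_t = sig_t + 1j * omega * EPSILON_0 * eps_t
        model = np.sqrt(s_t * (s_t * c2 + s_l * s2))
        r = (model - meas) * weights
        return np.concatenate([r.real, r.imag])

    sol = _scipy_least_squares(
        residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-12,
        max_nfev=max_iter * len(x0),
    )
    converged = bool(sol.status > 0)
    if not converged:
        raise RuntimeError(
            f"anisotropic fit did not converge at {frequency_hz} Hz: {sol.message}"
        )
    sig_l, sig_t, eps_l, eps_t = unpack(sol.x)
    residual = float(np.sqrt(2.0 * sol.cost))
    return AnisotropicVCP(
        frequency_hz=frequency_hz,
        sigma_L=float(sig_l),
        sigma_T=float(sig_t),
        eps_rL=float(eps_l),
        eps_rT=float(eps_t),
        fit_residual=residual,
        method="least_squares",
        converged=converged,
    )


def reconstruct_session(
    session: MeasurementSession,
    array: ElectrodeArray,
    sweep: FrequencySweep | None = None,
    isotropic_permittivity: bool = True,
    fiber_angle_deg: float = 0.0,
) -> tuple[ApparentVCP, VCPSpectrum]:
    """Full pipeline for one session: apparent VCP, then per-frequency fits.

    The session must be valid (complete direction×frequency grid, physical
    impedances); validation failures raise with all violations listed.
    Each frequency is fitted independently — no dispersion model is imposed
    at reconstruction time.
    """
    sweep = sweep if sweep is not None else FrequencySweep()
    violations = validate_session(session, array, sweep)
    if violations:
        raise ValueError("invalid session: " + "; ".join(violations))

    k_by_dir = {float(d): geometric_factor(array.config_for(d)) for d in array.directions}
    app = ApparentVCP()
    spectrum = VCPSpectrum()
    for f in sweep:
        omega = 2.0 * math.pi * f
        sigma_star_by_dir: dict[float, complex] = {}
        for d in array.directions:
            record = session.record_at(d, f)
            k = k_by_dir[float(d)]
            sigma, eps_r = apparent_vcp(record, k)
            app.add(d, f, sigma, eps_r)
            sigma_star_by_dir[float(d)] = complex(
                sigma, omega * EPSILON_0 * eps_r
            )
        spectrum.fits.append(
            least_squares_reconstruct(
                sigma_star_by_dir,
                frequency_hz=f,
                isotropic_permittivity=isotropic_permittivity,
                fiber_angle_deg=fiber_angle_deg,
            )
        )
    return app, spectrum
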