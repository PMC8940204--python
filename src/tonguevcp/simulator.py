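"""Synthetic measurement generator standing in for the device hardware.

Emulates the full measurement chain: a dispersive anisotropic tissue is
pushed through the half-space forward model, then through static per-channel
gain/offset errors and additive complex Gaussian noise, producing the same
session structure the physical device would.  Phantom (resistor-board)
readings are generated the same way for calibration testing.

Tissue dispersion uses a per-axis Cole model in complex-conductivity form,

    sigma*(omega) = sigma_inf − (sigma_inf − sigma_0) / (1 + (j omega tau)^alpha),

the minimal empirical description of the Maxwell–Wagner interfacial
polarization of myofiber membranes in the kHz range: conductivity rises and
relative permittivity falls with frequency, the trends seen in vivo.

All randomness flows from a single integer seed; identical seeds and inputs
give byte-identical sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import RawReading, TEPEBoard
from .forward import transfer_impedance_complex
from .geometry import (
    EPSILON_0,
    ElectrodeArray,
    FrequencySweep,
    MeasurementRecord,
    MeasurementSession,
    build_default_array,
)

__all__ = [
    "ColeAxisModel",
    "DispersiveTissue",
    "NoiseModel",
    "HEALTHY_TISSUE",
    "NOISELESS",
    "DEFAULT_NOISE",
    "cole_complex_conductivity",
    "draw_channel_errors",
    "simulate_session",
    "simulate_tepe",
]


@dataclass(frozen=True)
class ColeAxisModel:
    """Cole dispersion parameters for one tissue axis.

    sigma_0 and sigma_inf are the low- and high-frequency conductivity
    limits (S/m), tau the relaxation time (s), alpha in (0, 1] the
    dispersion broadness (alpha = 1 is a single-time-constant Debye-type
    relaxation).
    """

    sigma_0: float
    sigma_inf: float
    tau: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma_0 < self.sigma_inf):
            raise ValueError("require 0 < sigma_0 < sigma_inf")
        if self.tau <= 0:
            raise ValueError("relaxation time must be positive")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")


@dataclass(frozen=True)
class DispersiveTissue:
    """Anisotropic tissue with independent Cole dispersion per axis."""

    longitudinal: ColeAxisModel
    transverse: ColeAxisModel
    fiber_angle_deg: float = 0.0


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic model of the measurement chain.

    relative_sigma is the standard deviation of the additive complex
    Gaussian noise relative to |Z| (split evenly between the real and
    imaginary components); gain_error_sigma and offset_error_ohm
    parameterize static per-channel complex gain and offset errors, drawn
    once per direction.
    """

    relative_sigma: float = 0.0
    gain_error_sigma: float = 0.0
    offset_error_ohm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.relative_sigma, self.gain_error_sigma, self.offset_error_ohm) < 0:
            raise ValueError("noise magnitudes must be non-negative")


NOISELESS = NoiseModel()

#: Frozen convention for the device-like noise floor: 0.5 % complex noise on
#: Z plus 1 % static channel gain error and 1 Ω offset error.
DEFAULT_NOISE = NoiseModel(relative_sigma=0.005, gain_error_sigma=0.01,
                           offset_error_ohm=1.0, seed=0)

#: Healthy-tongue-like preset.  Both axes share the dispersion magnitude
#: (sigma_inf − sigma_0 = 0.2 S/m) and relaxation time (2 µs), so the
#: per-axis relative permittivities coincide at every frequency — matching
#: the angular symmetry of permittivity observed in vivo — while the
#: conductivities are strongly anisotropic.  Parameters chosen so the
#: default array sees |Z| within the in vivo 100–300 Ω band; frozen.
HEALTHY_TISSUE = DispersiveTissue(
    longitudinal=ColeAxisModel(sigma_0=0.6, sigma_inf=0.8, tau=2e-6, alpha=1.0),
    transverse=ColeAxisModel(sigma_0=0.3, sigma_inf=0.5, tau=2e-6, alpha=1.0),
)

TISSUE_PRESETS = {"healthy": HEALTHY_TISSUE}


def cole_complex_conductivity(axis: ColeAxisModel, frequency_hz: float) -> complex:
    """Evaluate the Cole complex conductivity at one frequency."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    jot = 1j * 2.0 * math.pi * frequency_hz * axis.tau
    delta = axis.sigma_inf - axis.sigma_0
    return axis.sigma_inf - delta / (1.0 + jot**axis.alpha)


def tissue_conductivities(
    tissue: DispersiveTissue, frequency_hz: float
) -> tuple[complex, complex]:
    """Per-axis (longitudinal, transverse) complex conductivities."""
    return (
        cole_complex_conductivity(tissue.longitudinal, frequency_hz),
        cole_complex_conductivity(tissue.transverse, frequency_hz),
    )


def tissue_eps_r(axis: ColeAxisModel, frequency_hz: float) -> float:
    """Relative permittivity implied by the Cole model: Im(sigma*)/(omega eps0)."""
    omega = 2.0 * math.pi * frequency_hz
    return cole_complex_conductivity(axis, frequency_hz).imag / (omega * EPSILON_0)


def _complex_normal(rng: np.random.Generator) -> complex:
    # unit-variance circular complex Gaussian
    return (rng.standard_normal() + 1j * rng.standard_normal()) / math.sqrt(2.0)


def draw_channel_errors(
    noise: NoiseModel,
    directions: tuple[float, ...],
    rng: np.random.Generator,
) -> dict[float, tuple[complex, complex]]:
    """Draw the static per-direction (gain, offset) channel errors once."""
    errors = {}
    for d in directions:
        gain = 1.0 + noise.gain_error_sigma * _complex_normal(rng)
        offset = noise.offset_error_ohm * _complex_normal(rng)
        errors[float(d)] = (gain, offset)
    return errors


def simulate_session(
    tissue: DispersiveTissue,
    array: ElectrodeArray | None = None,
    sweep: FrequencySweep | None = None,
    noise: NoiseModel = NOISELESS,
    subject_id: str = "sim-subject",
    operator_id: str = "sim-operator",
    device_id: str = "sim-utes",
    timestamp: str = "1970-01-01T00:00:00Z",
    channel_errors: dict[float, tuple[complex, complex]] | None = None,
) -> tuple[MeasurementSession, MeasurementSession]:
    """Simulate one full measurement; returns (raw session, truth session).

    The truth session holds the exact forward-model transfer impedances
    (calibrated flag set); the raw session holds gain*Z + offset + noise
    with the per-channel gain/offset drawn once per direction from the
    noise model's seeded generator (or supplied explicitly so a matching
    phantom simulation can share them).
    """
    array = array if array is not None else build_default_array()
    sweep = sweep if sweep is not None else FrequencySweep()
    rng = np.random.default_rng(noise.seed)
    if channel_errors is None:
        channel_errors = draw_channel_errors(noise, array.directions, rng)

    truth_records: list[MeasurementRecord] = []
    raw_records: list[MeasurementRecord] = []
    for direction in array.directions:
        cfg = array.config_for(direction)
        gain, offset = channel_errors[float(direction)]
        for f in sweep:
            s_l, s_t = tissue_conductivities(tissue, f)
            z = transfer_impedance_complex(cfg, s_l, s_t, tissue.fiber_angle_deg)
            truth_records.append(MeasurementRecord(direction, f, z, calibrated=True))
            raw = gain * z + offset
            if noise.relative_sigma > 0:
                raw = raw + noise.relative_sigma * abs(z) * _complex_normal(rng)
            raw_records.append(MeasurementRecord(direction, f, raw, calibrated=False))

    def make(records, calibrated_suffix):
        return MeasurementSession(
            subject_id=subject_id,
            operator_id=operator_id,
            device_id=device_id + calibrated_suffix,
            timestamp=timestamp,
            records=sorted(records, key=lambda r: (r.direction_deg, r.frequency_hz)),
        )

    return make(raw_records, ""), make(truth_records, "")


def simulate_tepe(
    board: TEPEBoard,
    sweep: FrequencySweep | None = None,
    noise: NoiseModel = NOISELESS,
    channel_errors: dict[float, tuple[complex, complex]] | None = None,
) -> list[tuple[RawReading, complex]]:
    """Simulate phantom-board readings paired with their known references.

    raw = gain*R + offset + noise per (direction, frequency); the returned
    pairs feed ``fit_calibration`` directly.  Passing the same
    ``channel_errors`` used for a session simulation reproduces the exact
    channel state the calibration must undo.
    """
    sweep = sweep if sweep is not None else FrequencySweep()
    rng = np.random.default_rng(noise.seed + 1)  # decorrelated from session noise
    directions = tuple(sorted(board.resistors_ohm))
    if channel_errors is None:
        channel_errors = draw_channel_errors(noise, directions, rng)
    out: list[tuple[RawReading, complex]] = []
    for direction in directions:
        r = board.resistors_ohm[direction]
        gain, offset = channel_errors[float(direction)]
        for f in sweep:
            raw = gain * r + offset
            if noise.relative_sigma > 0:
                raw = raw + noise.relative_sigma * abs(raw) * _complex_normal(rng)
            out.append((RawReading(direction, f, raw), complex(r)))
    return out
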