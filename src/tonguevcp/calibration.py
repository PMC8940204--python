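"""Resistor-phantom calibration of the measurement channels.

The device is calibrated against a phantom board carrying one known
surface-mount resistor per measuring direction (nominal range 100–1500 Ω,
spanning healthy and diseased tongue impedance values).  Each channel
(direction) at each excitation frequency is modelled as a complex linear
map of the true impedance,

    raw = gain * Z_ref + offset,

fitted by least squares.  With a single phantom board there is one reference
per channel, so only the gain is identifiable and the offset is fixed at
zero; two or more boards with distinct resistors determine gain and offset
jointly.  Reference resistors are treated as ideal: purely real and
frequency-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import MeasurementRecord

__all__ = [
    "TEPEBoard",
    "CalibrationTable",
    "RawReading",
    "fit_calibration",
    "apply_calibration",
    "phantom_accuracy_sweep",
]


@dataclass(frozen=True)
class TEPEBoard:
    """A tongue-electrical-properties-emulator board: one resistor per direction."""

    resistors_ohm: dict[float, float]
    board_id: str = "tepe"
    admissible_range_ohm: tuple[float, float] = (50.0, 2500.0)

    def __post_init__(self) -> None:
        lo, hi = self.admissible_range_ohm
        for d, r in self.resistors_ohm.items():
            if not (r > 0 and lo <= r <= hi):
                raise ValueError(
                    f"resistor {r} Ω at direction {d}° outside admissible "
                    f"range [{lo}, {hi}] Ω"
                )


@dataclass(frozen=True)
class RawReading:
    """Uncalibrated instrument output at one (direction, frequency) cell."""

    direction_deg: float
    frequency_hz: float
    raw: complex

    def __post_init__(self) -> None:
        if not (math.isfinite(self.raw.real) and math.isfinite(self.raw.imag)):
            raise ValueError("raw reading must be finite")


@dataclass
class CalibrationTable:
    """Per-(direction, frequency) complex gain/offset with fit residuals."""

    entries: dict[tuple[float, float], tuple[complex, complex]]
    residuals: dict[tuple[float, float], float] = field(default_factory=dict)
    device_id: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        for key, (gain, _) in self.entries.items():
            if abs(gain) == 0.0:
                raise ValueError(f"zero gain at {key}")

    def entry(self, direction_deg: float, frequency_hz: float) -> tuple[complex, complex]:
        key = (float(direction_deg), float(frequency_hz))
        if key not in self.entries:
            raise KeyError(f"no calibration entry at ({direction_deg}°, {frequency_hz} Hz)")
        return self.entries[key]


def fit_calibration(
    readings: list[tuple[RawReading, complex]],
    device_id: str = "",
    timestamp: str = "",
) -> CalibrationTable:
    """Fit the complex linear channel model from (raw, reference) pairs.

    Each (direction, frequency) cell is fitted independently.  Cells with a
    single reference point get a gain-only fit (offset pinned at 0); cells
    with two or more distinct references get the full least-squares
    gain+offset fit.  The per-cell residual norm is stored for diagnostics.

    Raises
    ------
    ValueError
        If a cell has no readings (caller passed an empty list), or if a
        multi-point cell has no two distinct reference values (singular fit).
    """
    if not readings:
        raise ValueError("no calibration readings supplied")
    cells: dict[tuple[float, float], list[tuple[complex, complex]]] = {}
    for reading, z_ref in readings:
        key = (float(reading.direction_deg), float(reading.frequency_hz))
        cells.setdefault(key, []).append((reading.raw, complex(z_ref)))

    entries: dict[tuple[float, float], tuple[complex, complex]] = {}
    residuals: dict[tuple[float, float], float] = {}
    for key, pairs in cells.items():
        raw = np.array([p[0] for p in pairs], dtype=complex)
        ref = np.array([p[1] for p in pairs], dtype=complex)
        if len(pairs) == 1:
            if ref[0] == 0:
                raise ValueError(f"zero reference impedance at {key}")
            gain = raw[0] / ref[0]
            offset = 0.0 + 0.0j
            res = 0.0
        else:
            if np.allclose(ref, ref[0]):
                raise ValueError(
                    f"duplicate reference values at {key}: gain+offset fit is singular"
                )
            design = np.column_stack([ref, np.ones_like(ref)])
            coef, *_ = np.linalg.lstsq(design, raw, rcond=None)
            gain, offset = complex(coef[0]), complex(coef[1])
            res = float(np.linalg.norm(design @ coef - raw))
        if abs(gain) == 0.0:
            raise ValueError(f"fitted zero gain at {key}")
        entries[key] = (complex(gain), offset)
        residuals[key] = res
    return CalibrationTable(entries=entries, residuals=residuals,
                            device_id=device_id, timestamp=timestamp)


def apply_calibration(reading: RawReading, table: CalibrationTable) -> MeasurementRecord:
    """Invert the channel model: z = (raw − offset) / gain."""
    gain, offset = table.entry(reading.direction_deg, reading.frequency_hz)
    z = (reading.raw - offset) / gain
    return MeasurementRecord(
        direction_deg=reading.direction_deg,
        frequency_hz=reading.frequency_hz,
        z=z,
        calibrated=True,
    )


def phantom_accuracy_sweep(
    boards: list[TEPEBoard],
    table: CalibrationTable,
    noise_model,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulated accuracy characterization over a set of phantom boards.

    Each board resistor is pushed through the channel model stored in the
    calibration table (raw = gain*R + offset) with additive complex Gaussian
    measurement noise, then calibrated back; the absolute relative error
    |z_cal − R| / R is reported per (direction, frequency, resistance) cell.
    This reproduces the structure of the device's accuracy chart: error
    growing with noise relative to the measured magnitude.

    ``noise_model`` needs a ``relative_sigma`` attribute (std of the complex
    Gaussian noise relative to |raw|); its channel gain/offset errors do not
    apply here because the table itself plays the channel.
    """
    if not boards:
        raise ValueError("empty board list")
    rng = np.random.default_rng(seed if seed is not None else noise_model.seed)
    rows = []
    for board in boards:
        for (direction, frequency), (gain, offset) in sorted(table.entries.items()):
            if direction not in board.resistors_ohm:
                continue
            r = board.resistors_ohm[direction]
            raw = gain * r + offset
            if noise_model.relative_sigma > 0:
                scale = noise_model.relative_sigma * abs(raw) / math.sqrt(2.0)
                raw = raw + scale * (rng.standard_normal() + 1j * rng.standard_normal())
            z = (raw - offset) / gain
            rows.append(
                {
                    "board_id": board.board_id,
                    "direction_deg": direction,
                    "frequency_hz": frequency,
                    "resistance_ohm": r,
                    "relative_error": abs(z - r) / r,
                }
            )
    return pd.DataFrame(rows)
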