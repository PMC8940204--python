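"""Electrode-array geometry, tetrapolar configurations, and session containers.

The tongue depressor carries 16 surface contacts arranged on two concentric
circles (radii 4 mm and 7 mm by default).  Each measuring direction
(0°, 45°, 90°, 150°) uses a collinear tetrapolar quadruple: a current pair
A/B on one ring and a voltage pair M/N on the other.  All electrodes are
treated as ideal points on the tissue surface plane (z = 0); finite contact
area and electrode polarization are not modelled.

Units are SI throughout (metres, hertz, ohms).  Angles are degrees measured
counter-clockwise from the 0° sagittal axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "EPSILON_0",
    "DEFAULT_DIRECTIONS_DEG",
    "DEFAULT_FREQUENCIES_HZ",
    "SurfacePoint",
    "TetrapolarConfig",
    "ElectrodeArray",
    "FrequencySweep",
    "MeasurementRecord",
    "MeasurementSession",
    "build_default_array",
    "validate_session",
]

#: Vacuum permittivity, F/m.
EPSILON_0 = 8.8541878128e-12

DEFAULT_DIRECTIONS_DEG = (0.0, 45.0, 90.0, 150.0)
DEFAULT_FREQUENCIES_HZ = (8000.0, 16000.0, 32000.0, 64000.0, 128000.0, 256000.0)

#: Collinearity tolerance for tetrapolar quadruples, metres.
_COLLINEAR_TOL_M = 1e-9


@dataclass(frozen=True)
class SurfacePoint:
    """A point on the tissue surface plane; x runs along the 0° sagittal axis."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite surface point ({self.x}, {self.y})")

    def rotated(self, angle_deg: float) -> "SurfacePoint":
        """Rotate counter-clockwise about the origin."""
        a = math.radians(angle_deg)
        c, s = math.cos(a), math.sin(a)
        return SurfacePoint(c * self.x - s * self.y, s * self.x + c * self.y)

    def distance_to(self, other: "SurfacePoint") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class TetrapolarConfig:
    """Collinear four-electrode configuration at one measuring direction.

    Current is injected through A (source) and B (sink); the potential
    difference is sensed between M (+) and N (−).  All four points must be
    distinct and collinear with the direction vector (cos θ, sin θ).
    """

    direction_deg: float
    A: SurfacePoint
    B: SurfacePoint
    M: SurfacePoint
    N: SurfacePoint

    def __post_init__(self) -> None:
        pts = (self.A, self.B, self.M, self.N)
        for i in range(4):
            for j in range(i + 1, 4):
                if pts[i].distance_to(pts[j]) == 0.0:
                    raise ValueError("tetrapolar electrodes must be distinct")
        a = math.radians(self.direction_deg)
        ux, uy = math.cos(a), math.sin(a)
        ref = self.A
        for p in pts[1:]:
            # perpendicular distance of (p - ref) from the direction axis
            cross = abs((p.x - ref.x) * uy - (p.y - ref.y) * ux)
            if cross > _COLLINEAR_TOL_M:
                raise ValueError(
                    f"electrodes not collinear with direction {self.direction_deg}° "
                    f"(offset {cross:.3e} m)"
                )

    @property
    def electrodes(self) -> tuple[SurfacePoint, ...]:
        return (self.A, self.B, self.M, self.N)


@dataclass(frozen=True)
class ElectrodeArray:
    """The full multi-directional surface array (16 contacts by default)."""

    inner_radius: float = 0.004
    outer_radius: float = 0.007
    directions: tuple[float, ...] = DEFAULT_DIRECTIONS_DEG
    configs: tuple[TetrapolarConfig, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.inner_radius < self.outer_radius):
            raise ValueError(
                "require 0 < inner_radius < outer_radius, got "
                f"{self.inner_radius} and {self.outer_radius}"
            )

    def config_for(self, direction_deg: float) -> TetrapolarConfig:
        for cfg in self.configs:
            if math.isclose(cfg.direction_deg, direction_deg, abs_tol=1e-9):
                return cfg
        raise KeyError(f"no tetrapolar configuration at {direction_deg}°")

    @property
    def contacts(self) -> list[SurfacePoint]:
        out: list[SurfacePoint] = []
        for cfg in self.configs:
            out.extend(cfg.electrodes)
        return out


@dataclass(frozen=True)
class FrequencySweep:
    """Stepped-sine excitation frequencies, strictly increasing."""

    frequencies_hz: tuple[float, ...] = DEFAULT_FREQUENCIES_HZ

    def __post_init__(self) -> None:
        f = self.frequencies_hz
        if len(f) == 0 or any(x <= 0 for x in f):
            raise ValueError("frequencies must be positive")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("frequencies must be strictly increasing")

    def __iter__(self):
        return iter(self.frequencies_hz)

    def __len__(self) -> int:
        return len(self.frequencies_hz)


@dataclass(frozen=True)
class MeasurementRecord:
    """One complex transfer impedance at (direction, frequency).

    ``z`` is in ohms: real part = resistance R, imaginary part = reactance X.
    """

    direction_deg: float
    frequency_hz: float
    z: complex
    calibrated: bool = False


@dataclass
class MeasurementSession:
    """A complete multi-directional, multi-frequency measurement.

    Mirrors the device's emailed data file: subject/operator/device
    identifiers, timestamp, optional battery level and firmware version, and
    one record per (direction, frequency) cell.
    """

    subject_id: str
    operator_id: str
    device_id: str
    timestamp: str
    records: list[MeasurementRecord]
    schema_version: str = "1"
    battery_level: float | None = None
    firmware_version: str | None = None
    extra: dict = field(default_factory=dict)

    def sorted_records(self) -> list[MeasurementRecord]:
        return sorted(self.records, key=lambda r: (r.direction_deg, r.frequency_hz))

    def record_at(self, direction_deg: float, frequency_hz: float) -> MeasurementRecord:
        for r in self.records:
            if (
                math.isclose(r.direction_deg, direction_deg, abs_tol=1e-9)
                and math.isclose(r.frequency_hz, frequency_hz, rel_tol=1e-12)
            ):
                return r
        raise KeyError(f"no record at ({direction_deg}°, {frequency_hz} Hz)")


def build_default_array(
    inner_radius: float = 0.004,
    outer_radius: float = 0.007,
    directions: tuple[float, ...] = DEFAULT_DIRECTIONS_DEG,
    current_ring: str = "outer",
) -> ElectrodeArray:
    """Build the concentric-ring array with one tetrapolar config per direction.

    For each direction θ the four contacts are the 0°-axis quadruple
    (±outer, 0) and (±inner, 0) rotated by θ.  By default the outer-ring
    pair carries current (A/B) and the inner-ring pair senses voltage (M/N),
    the symmetric collinear arrangement that keeps the sensing dipole inside
    the current path; ``current_ring="inner"`` flips the role assignment.
    """
    if current_ring not in ("outer", "inner"):
        raise ValueError("current_ring must be 'outer' or 'inner'")
    if not (0.0 < inner_radius < outer_radius):
        raise ValueError("require 0 < inner_radius < outer_radius")
    configs = []
    for theta in directions:
        outer_neg = SurfacePoint(-outer_radius, 0.0).rotated(theta)
        outer_pos = SurfacePoint(outer_radius, 0.0).rotated(theta)
        inner_neg = SurfacePoint(-inner_radius, 0.0).rotated(theta)
        inner_pos = SurfacePoint(inner_radius, 0.0).rotated(theta)
        if current_ring == "outer":
            cfg = TetrapolarConfig(theta, A=outer_neg, B=outer_pos, M=inner_neg, N=inner_pos)
        else:
            cfg = TetrapolarConfig(theta, A=inner_neg, B=inner_pos, M=outer_neg, N=outer_pos)
        configs.append(cfg)
    return ElectrodeArray(
        inner_radius=inner_radius,
        outer_radius=outer_radius,
        directions=tuple(directions),
        configs=tuple(configs),
    )


def validate_session(
    session: MeasurementSession,
    array: ElectrodeArray,
    sweep: FrequencySweep,
) -> list[str]:
    """Check a session against the array/sweep grid; return violation messages.

    An empty list means the session is valid: identifiers non-empty, exactly
    one record per (direction, frequency) cell, and every impedance finite
    with positive magnitude.  Violations are reported, never raised, so a
    caller can surface all problems at once.
    """
    violations: list[str] = []
    if not session.subject_id:
        violations.append("subject_id is empty")
    if not session.operator_id:
        violations.append("operator_id is empty")

    counts: dict[tuple[float, float], int] = {}
    for r in session.records:
        key = (float(r.direction_deg), float(r.frequency_hz))
        counts[key] = counts.get(key, 0) + 1
        if not (math.isfinite(r.z.real) and math.isfinite(r.z.imag)) or abs(r.z) == 0.0:
            violations.append(
                f"non-physical impedance |z|={abs(r.z)} at "
                f"({r.direction_deg}°, {r.frequency_hz} Hz)"
            )

    expected = {
        (float(d), float(f)) for d in array.directions for f in sweep.frequencies_hz
    }
    for d, f in sorted(expected - set(counts)):
        violations.append(f"missing record at ({d}°, {f} Hz)")
    for (d, f), n in sorted(counts.items()):
        if (d, f) not in expected:
            violations.append(f"unexpected record at ({d}°, {f} Hz)")
        elif n > 1:
            violations.append(f"duplicate records ({n}) at ({d}°, {f} Hz)")
    return violations
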