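"""JSON file formats: sessions, calibration tables, phantoms, geometry.

One session per JSON file, self-describing and small (24 records for the
default grid), mirroring the device's emailed data file.  Schema checks are
field-level and name the offending record index.  Unknown top-level and
per-record fields are preserved on a read/write round trip; records are
written sorted by direction then frequency so identical sessions serialize
byte-identically.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from .calibration import CalibrationTable, RawReading, TEPEBoard
from .geometry import (
    DEFAULT_DIRECTIONS_DEG,
    ElectrodeArray,
    MeasurementRecord,
    MeasurementSession,
    build_default_array,
)

__all__ = [
    "SchemaError",
    "read_session",
    "write_session",
    "read_calibration_table",
    "write_calibration_table",
    "read_phantom",
    "write_phantom",
    "read_geometry",
    "write_geometry",
    "read_tepe_readings",
    "write_tepe_readings",
]

_SESSION_REQUIRED = ("schema_version", "subject_id", "operator_id", "device_id",
                     "timestamp", "records")
_RECORD_REQUIRED = ("direction_deg", "frequency_hz", "z_real_ohm", "z_imag_ohm")
_SESSION_KNOWN = set(_SESSION_REQUIRED) | {"battery_level", "firmware_version"}
_RECORD_KNOWN = set(_RECORD_REQUIRED) | {"calibrated"}


class SchemaError(ValueError):
    """A file failed schema validation; the message names the field."""


def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise SchemaError(f"{where}: missing required field '{key}'")
    return obj[key]


def _number(value, key: str, where: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise SchemaError(f"{where}: field '{key}' must be a number, got {value!r}")
    if not math.isfinite(float(value)):
        raise SchemaError(f"{where}: field '{key}' must be finite")
    return float(value)


def read_session(path: str | Path) -> MeasurementSession:
    """Read and validate a session file."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: session file must hold a JSON object")
    where = str(path)
    for key in _SESSION_REQUIRED:
        _require(data, key, where)
    records_raw = data["records"]
    if not isinstance(records_raw, list):
        raise SchemaError(f"{where}: 'records' must be a list")
    records = []
    for i, rec in enumerate(records_raw):
        rwhere = f"{where}: record {i}"
        if not isinstance(rec, dict):
            raise SchemaError(f"{rwhere} must be an object")
        for key in _RECORD_REQUIRED:
            _require(rec, key, rwhere)
        records.append(
            MeasurementRecord(
                direction_deg=_number(rec["direction_deg"], "direction_deg", rwhere),
                frequency_hz=_number(rec["frequency_hz"], "frequency_hz", rwhere),
                z=complex(
                    _number(rec["z_real_ohm"], "z_real_ohm", rwhere),
                    _number(rec["z_imag_ohm"], "z_imag_ohm", rwhere),
                ),
                calibrated=bool(rec.get("calibrated", False)),
            )
        )
    extra = {k: v for k, v in data.items() if k not in _SESSION_KNOWN}
    battery = data.get("battery_level")
    return MeasurementSession(
        schema_version=str(data["schema_version"]),
        subject_id=str(data["subject_id"]),
        operator_id=str(data["operator_id"]),
        device_id=str(data["device_id"]),
        timestamp=str(data["timestamp"]),
        battery_level=None if battery is None else _number(battery, "battery_level", where),
        firmware_version=(None if data.get("firmware_version") is None
                          else str(data["firmware_version"])),
        records=records,
        extra=extra,
    )


def write_session(session: MeasurementSession, path: str | Path) -> None:
    """Write a session file; records sorted by direction then frequency."""
    doc: dict = {
        "schema_version": session.schema_version,
        "subject_id": session.subject_id,
        "operator_id": session.operator_id,
        "device_id": session.device_id,
        "timestamp": session.timestamp,
    }
    if session.battery_level is not None:
        doc["battery_level"] = session.battery_level
    if session.firmware_version is not None:
        doc["firmware_version"] = session.firmware_version
    doc.update(sorted(session.extra.items()))
    doc["records"] = [
        {
            "direction_deg": r.direction_deg,
            "frequency_hz": r.frequency_hz,
            "z_real_ohm": r.z.real,
            "z_imag_ohm": r.z.imag,
            "calibrated": r.calibrated,
        }
        for r in session.sorted_records()
    ]
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_calibration_table(table: CalibrationTable, path: str | Path) -> None:
    doc = {
        "schema_version": "1",
        "device_id": table.device_id,
        "timestamp": table.timestamp,
        "entries": [
            {
                "direction_deg": d,
                "frequency_hz": f,
                "gain_real": g.real,
                "gain_imag": g.imag,
                "offset_real_ohm": o.real,
                "offset_imag_ohm": o.imag,
                "residual": table.residuals.get((d, f), 0.0),
            }
            for (d, f), (g, o) in sorted(table.entries.items())
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_calibration_table(path: str | Path) -> CalibrationTable:
    with open(path) as fh:
        data = json.load(fh)
    where = str(path)
    entries = {}
    residuals = {}
    for i, e in enumerate(_require(data, "entries", where)):
        ewhere = f"{where}: entry {i}"
        key = (
            _number(_require(e, "direction_deg", ewhere), "direction_deg", ewhere),
            _number(_require(e, "frequency_hz", ewhere), "frequency_hz", ewhere),
        )
        entries[key] = (
            complex(e.get("gain_real", 1.0), e.get("gain_imag", 0.0)),
            complex(e.get("offset_real_ohm", 0.0), e.get("offset_imag_ohm", 0.0)),
        )
        residuals[key] = float(e.get("residual", 0.0))
    return CalibrationTable(
        entries=entries,
        residuals=residuals,
        device_id=str(data.get("device_id", "")),
        timestamp=str(data.get("timestamp", "")),
    )


def write_phantom(board: TEPEBoard, path: str | Path) -> None:
    doc = {
        "board_id": board.board_id,
        "resistors_ohm": {str(d): r for d, r in sorted(board.resistors_ohm.items())},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_phantom(path: str | Path) -> TEPEBoard:
    with open(path) as fh:
        data = json.load(fh)
    where = str(path)
    resistors_raw = _require(data, "resistors_ohm", where)
    resistors = {
        float(d): _number(r, f"resistors_ohm[{d}]", where)
        for d, r in resistors_raw.items()
    }
    return TEPEBoard(resistors_ohm=resistors, board_id=str(data.get("board_id", "tepe")))


def write_geometry(array: ElectrodeArray, path: str | Path,
                   current_ring: str = "outer") -> None:
    doc = {
        "inner_radius_mm": array.inner_radius * 1e3,
        "outer_radius_mm": array.outer_radius * 1e3,
        "directions_deg": list(array.directions),
        "current_ring": current_ring,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_geometry(path: str | Path) -> ElectrodeArray:
    """Read a geometry config; radii are millimetres with explicit unit tag."""
    with open(path) as fh:
        data = json.load(fh)
    where = str(path)
    inner_mm = _number(_require(data, "inner_radius_mm", where), "inner_radius_mm", where)
    outer_mm = _number(_require(data, "outer_radius_mm", where), "outer_radius_mm", where)
    directions = tuple(
        _number(d, "directions_deg", where)
        for d in data.get("directions_deg", DEFAULT_DIRECTIONS_DEG)
    )
    ring = str(data.get("current_ring", "outer"))
    return build_default_array(
        inner_radius=inner_mm * 1e-3,
        outer_radius=outer_mm * 1e-3,
        directions=directions,
        current_ring=ring,
    )


def write_tepe_readings(
    readings: list[tuple[RawReading, complex]], path: str | Path
) -> None:
    doc = {
        "schema_version": "1",
        "readings": [
            {
                "direction_deg": r.direction_deg,
                "frequency_hz": r.frequency_hz,
                "raw_real": r.raw.real,
                "raw_imag": r.raw.imag,
                "reference_ohm": ref.real,
            }
            for r, ref in readings
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_tepe_readings(path: str | Path) -> list[tuple[RawReading, complex]]:
    with open(path) as fh:
        data = json.load(fh)
    where = str(path)
    out = []
    for i, e in enumerate(_require(data, "readings", where)):
        ewhere = f"{where}: reading {i}"
        out.append(
            (
                RawReading(
                    direction_deg=_number(_require(e, "direction_deg", ewhere),
                                          "direction_deg", ewhere),
                    frequency_hz=_number(_require(e, "frequency_hz", ewhere),
                                         "frequency_hz", ewhere),
                    raw=complex(
                        _number(_require(e, "raw_real", ewhere), "raw_real", ewhere),
                        _number(_require(e, "raw_imag", ewhere), "raw_imag", ewhere),
                    ),
                ),
                complex(_number(_require(e, "reference_ohm", ewhere),
                                "reference_ohm", ewhere)),
            )
        )
    return out
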