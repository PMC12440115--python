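"""Serialization of surface records to AERMET-compatible .sfc text files.

The dialect written here is whitespace-delimited with fixed decimal
precisions per field, matching the free-format read of AERMET-family
consumers: one header line carrying the station coordinates and identifiers,
then one line per hour with the 27 surface fields in canonical order. The
reader is the inverse on files this writer produced and is tolerant of
arbitrary extra whitespace, so it can also ingest external observation-based
.sfc files written in the same free format.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scenarios import SURFACE_COLUMNS


@dataclass
class SfcHeader:
    """One-line .sfc header: station location and identifier strings."""

    latitude: float
    longitude: float
    ua_id: str = "00000"
    sf_id: str = "00000"
    os_id: str = "00000"
    version_tag: str = "19191"

    def __post_init__(self) -> None:
        if not abs(self.latitude) <= 90:
            raise ValueError("|latitude| must be <= 90")
        if not abs(self.longitude) <= 180:
            raise ValueError("|longitude| must be <= 180")

    def to_line(self) -> str:
        ns = "N" if self.latitude >= 0 else "S"
        ew = "E" if self.longitude >= 0 else "W"
        return (
            f"{abs(self.latitude):8.3f}{ns} {abs(self.longitude):9.3f}{ew}"
            f"  UA_ID: {self.ua_id}  SF_ID: {self.sf_id}  OS_ID: {self.os_id}"
            f"  VERSION: {self.version_tag}"
        )


_HEADER_RE = re.compile(
    r"^\s*([\d.]+)([NS])\s+([\d.]+)([EW])"
    r"\s+UA_ID:\s*(\S+)\s+SF_ID:\s*(\S+)\s+OS_ID:\s*(\S+)\s+VERSION:\s*(\S+)\s*$"
)

# (column, format, parser); wind_direction is rounded to a whole degree on
# write, all other floats keep the stated decimal precision
_INT = ("{:d}", int)
_FIELD_FORMATS: list[tuple[str, str, type]] = [
    ("year", "{:2d}", int),
    ("month", "{:2d}", int),
    ("day", "{:2d}", int),
    ("julian_day", "{:3d}", int),
    ("hour", "{:2d}", int),
    ("sensible_heat", "{:8.1f}", float),
    ("friction_velocity", "{:7.4f}", float),
    ("w_star", "{:8.4f}", float),
    ("vptg_500m", "{:6.1f}", float),
    ("z_ic", "{:8.1f}", float),
    ("z_im", "{:8.1f}", float),
    ("obukhov_length", "{:8.1f}", float),
    ("surface_roughness", "{:7.4f}", float),
    ("bowen_ratio", "{:6.2f}", float),
    ("albedo", "{:5.2f}", float),
    ("wind_speed", "{:7.2f}", float),
    ("wind_direction", "{:4d}", int),
    ("wind_height", "{:6.1f}", float),
    ("temperature", "{:6.1f}", float),
    ("temperature_height", "{:5.1f}", float),
    ("precip_code", "{:3d}", int),
    ("precip_amount", "{:7.2f}", float),
    ("relative_humidity", "{:6.1f}", float),
    ("station_pressure", "{:9.1f}", float),
    ("cloud_cover", "{:3d}", int),
    ("adj_flag", "{}", str),
    ("sub_flag", "{}", str),
]

#: Decimal places preserved per float column (for round-trip tolerance).
WRITTEN_PRECISION: dict[str, int] = {
    "sensible_heat": 1, "friction_velocity": 4, "w_star": 4, "vptg_500m": 1,
    "z_ic": 1, "z_im": 1, "obukhov_length": 1, "surface_roughness": 4,
    "bowen_ratio": 2, "albedo": 2, "wind_speed": 2, "wind_height": 1,
    "temperature": 1, "temperature_height": 1, "precip_amount": 2,
    "relative_humidity": 1, "station_pressure": 1,
}


def _check_chronology(records: pd.DataFrame) -> None:
    keys = list(
        zip(records["year"], records["julian_day"], records["hour"], strict=True)
    )
    for prev, cur in zip(keys, keys[1:]):
        if cur <= prev:
            raise ValueError(
                f"records must be chronologically ordered without duplicates; "
                f"found {cur} after {prev}"
            )


def write_sfc(header: SfcHeader, records: pd.DataFrame, path: str | Path) -> None:
    """Write a surface-record table as a .sfc file (header + one line/hour)."""
    missing = [c for c in SURFACE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing columns: {missing}")
    _check_chronology(records)
    lines = [SfcHeader.to_line(header)]
    for _, row in records.iterrows():
        parts = []
        for col, fmt, kind in _FIELD_FORMATS:
            val = row[col]
            if kind is int and col == "wind_direction":
                val = int(round(float(val))) % 360
            elif kind is int:
                val = int(val)
            elif kind is float:
                val = float(val)
            parts.append(fmt.format(val))
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


_RANGES = {
    "month": (1, 12),
    "day": (1, 31),
    "julian_day": (1, 366),
    "hour": (1, 24),
    "cloud_cover": (0, 10),
}


def read_sfc(path: str | Path) -> tuple[SfcHeader, pd.DataFrame]:
    """Parse a .sfc file back into its header and surface-record table.

    Raises ``ValueError`` with a line number for a malformed header, a wrong
    column count, an unparseable token, or a field outside its valid range
    (e.g. hour not in 1-24).
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    m = _HEADER_RE.match(lines[0])
    if m is None:
        raise ValueError(f"{path}: line 1: malformed header")
    lat = float(m.group(1)) * (1 if m.group(2) == "N" else -1)
    lon = float(m.group(3)) * (1 if m.group(4) == "E" else -1)
    header = SfcHeader(lat, lon, m.group(5), m.group(6), m.group(7), m.group(8))

    rows: list[dict] = []
    for lineno, line in enumerate(lines[1:], start=2):
        tokens = line.split()
        if len(tokens) != len(_FIELD_FORMATS):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(_FIELD_FORMATS)} fields, "
                f"got {len(tokens)}"
            )
        row: dict = {}
        for (col, _fmt, kind), tok in zip(_FIELD_FORMATS, tokens, strict=True):
            try:
                row[col] = kind(tok) if kind is not int else int(float(tok))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: cannot parse {col!r} from {tok!r}"
                ) from exc
        for col, (lo, hi) in _RANGES.items():
            if not lo <= row[col] <= hi:
                raise ValueError(
                    f"{path}: line {lineno}: {col} = {row[col]} outside [{lo}, {hi}]"
                )
        if not 0 <= row["wind_direction"] < 360:
            raise ValueError(
                f"{path}: line {lineno}: wind_direction outside [0, 360)"
            )
        rows.append(row)
    records = pd.DataFrame(rows, columns=SURFACE_COLUMNS)
    return header, records


def roundtrip_tolerances() -> dict[str, float]:
    """Half-unit-in-last-written-place tolerance per float column."""
    return {col: 0.5 * 10.0 ** (-dp) + 1e-12 for col, dp in WRITTEN_PRECISION.items()}
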