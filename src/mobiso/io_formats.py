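"""Sensor-log parsing and cleaning.

Two dialects feed the pipeline:

* indoor UWB tag logs — one JSON message per line, carrying tag id, epoch
  timestamp, a success flag, 3-D local coordinates, a 3-axis accelerometer
  array, the mood-button state and the zone array, plus transport metadata
  (message ids, version strings, anchor diagnostics) that cleaning discards;
* outdoor GPS logs — NMEA-0183 ``$GPRMC`` sentences with UTC time, validity
  flag, ddmm.mmmm latitude/longitude with hemisphere letters, speed over
  ground in knots, true course and a ddmmyy date stamp.

Cleaning normalises every timestamp to "YYYY-MM-DD HH:MM:SS" wall-clock
form, drops messages whose position could not be measured (success=false),
and keeps an explicit drop report so record counts are conserved.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mobiso")

#: Local wall-clock offset from UTC applied when rendering indoor epoch
#: timestamps; the indoor day window (09:00-17:00) is defined in local time.
DEFAULT_UTC_OFFSET_HOURS = 0.0

#: Fields of the indoor message retained after cleaning; everything else
#: (error info, version, message id, anchor diagnostics) is metadata.
# header + time, status, lat, NS, lon, EW, speed, course, date, magvar, magvar E/W
GPRMC_FIELD_COUNT = 12


class MalformedRecordError(ValueError):
    """A sensor log line that cannot be parsed into a sample record."""


@dataclass(frozen=True)
class IndoorSample:
    """One cleaned indoor positioning message."""

    tag_id: str
    timestamp: float            # epoch seconds (fractional part kept)
    success: bool
    coords: tuple[float, float, float]   # local frame, millimetres
    accel: tuple[float, float, float]    # ax, ay, az
    status: int                 # 0 neutral / 1 happy / 2 sad (mood button)
    zones: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.accel) != 3:
            raise ValueError("accelerometer array must have exactly 3 components")
        if len(self.coords) != 3:
            raise ValueError("coordinates must be a 3-vector")
        if self.status not in (0, 1, 2):
            raise ValueError(f"status must be 0/1/2, got {self.status}")

    def datetime_str(self, utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS) -> str:
        """Timestamp normalised to 'YYYY-MM-DD HH:MM:SS' local wall clock."""
        dt = datetime.fromtimestamp(self.timestamp, tz=timezone.utc) + timedelta(
            hours=utc_offset_hours
        )
        return dt.strftime("%Y-%m-%d %H:%M:%S")


@dataclass(frozen=True)
class OutdoorSample:
    """One parsed ``$GPRMC`` fix."""

    time_utc: str        # hhmmss as printed
    date: str            # ddmmyy as printed
    valid: bool          # status letter 'A' (OK) vs 'V' (invalid)
    lat_raw: float       # ddmm.mmmm
    ns: str
    lon_raw: float       # dddmm.mmmm
    ew: str
    speed_kn: float      # speed over ground, knots
    course_deg: float    # true course, degrees clockwise from north
    datetime_str: str = field(default="", compare=True)

    def __post_init__(self) -> None:
        if self.speed_kn < 0:
            raise ValueError("speed over ground must be non-negative")
        if not (0 <= self.course_deg < 360):
            raise ValueError("course must lie in [0, 360)")

    @property
    def epoch(self) -> float:
        """Epoch seconds of the fix (UTC)."""
        dt = datetime.strptime(self.datetime_str, "%Y-%m-%d %H:%M:%S").replace(
            tzinfo=timezone.utc
        )
        return dt.timestamp()


@dataclass
class DropReport:
    """Accounting of what a parser kept, skipped or dropped.

    Invariant: ``parsed + skipped + dropped == total_lines``.
    """

    total_lines: int = 0
    parsed: int = 0
    skipped: int = 0   # unparseable or foreign lines (e.g. non-GPRMC sentences)
    dropped: int = 0   # parsed but excluded (success=false indoor messages)

    def conserves(self) -> bool:
        return self.parsed + self.skipped + self.dropped == self.total_lines


def _normalize_gprmc_datetime(time_utc: str, date: str) -> str:
    """Combine hhmmss + ddmmyy into 'YYYY-MM-DD HH:MM:SS' (2-digit years → 2000s)."""
    if len(time_utc) < 6 or len(date) != 6:
        raise MalformedRecordError(f"bad time/date fields {time_utc!r}/{date!r}")
    hh, mm, ss = time_utc[0:2], time_utc[2:4], time_utc[4:6]
    dd, mo, yy = date[0:2], date[2:4], date[4:6]
    try:
        dt = datetime(2000 + int(yy), int(mo), int(dd), int(hh), int(mm), int(ss))
    except ValueError as e:
        raise MalformedRecordError(f"invalid time/date {time_utc!r}/{date!r}: {e}") from e
    return dt.strftime("%Y-%m-%d %H:%M:%S")


def parse_gprmc(line: str) -> OutdoorSample:
    """Parse one ``$GPRMC`` sentence into an :class:`OutdoorSample`.

    A 'V' (invalid) status letter is parsed, not rejected: the fix is kept
    with ``valid=False`` so dwell accounting can still see it, and distance
    and speed computations exclude it downstream. A trailing ``*hh``
    checksum is tolerated but not verified.
    """
    line = line.strip()
    if not line.startswith("$GPRMC"):
        raise MalformedRecordError(f"not a $GPRMC sentence: {line[:20]!r}")
    body = line.split("*", 1)[0]  # drop optional checksum
    fields = body.split(",")
    if len(fields) != GPRMC_FIELD_COUNT:
        raise MalformedRecordError(
            f"expected {GPRMC_FIELD_COUNT} comma fields, got {len(fields)}"
        )
    (_, time_utc, status, lat_raw, ns, lon_raw, ew,
     speed, course, date, _magvar, _magvar_ew) = fields

    if status not in ("A", "V"):
        raise MalformedRecordError(f"validity flag must be A or V, got {status!r}")
    try:
        lat = float(lat_raw)
        lon = float(lon_raw)
        speed_kn = float(speed) if speed else 0.0
        course_deg = float(course) if course else 0.0
    except ValueError as e:
        raise MalformedRecordError(f"non-numeric field in {line!r}") from e
    course_deg = course_deg % 360.0

    return OutdoorSample(
        time_utc=time_utc,
        date=date,
        valid=(status == "A"),
        lat_raw=lat,
        ns=ns,
        lon_raw=lon,
        ew=ew,
        speed_kn=speed_kn,
        course_deg=course_deg,
        datetime_str=_normalize_gprmc_datetime(time_utc, date),
    )


def read_nmea_log(path) -> tuple[list[OutdoorSample], DropReport]:
    """Read a text file of NMEA sentences; non-GPRMC sentence types are skipped with count."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = DropReport()
    samples: list[OutdoorSample] = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        report.total_lines += 1
        if not line.startswith("$GPRMC"):
            report.skipped += 1
            continue
        try:
            samples.append(parse_gprmc(line))
            report.parsed += 1
        except MalformedRecordError:
            logger.warning("skipping malformed NMEA line: %.60s", line)
            report.skipped += 1
    return samples, report


# indoor message keys that survive cleaning; all other top-level / tagData
# keys (errorInfo, version, messageId, blinkIndex, anchorData, ...) are
# transport metadata and are discarded
def _parse_pozyx_message(obj: dict) -> IndoorSample:
    data = obj.get("data", {})
    tag_data = data.get("tagData", {})
    coords = data.get("coordinates")
    if isinstance(coords, dict):
        coords = [coords.get("x"), coords.get("y"), coords.get("z", 0.0)]
    accel = tag_data.get("accelerometer")
    zones_raw = data.get("zones", [])
    zones = tuple(
        (int(z.get("id", i)), str(z.get("name", ""))) for i, z in enumerate(zones_raw)
    )
    if coords is None or accel is None:
        raise MalformedRecordError("message lacks coordinates or accelerometer")
    ts = float(obj["timestamp"])
    if ts > 1e12:  # epoch milliseconds → seconds
        ts /= 1000.0
    return IndoorSample(
        tag_id=str(obj["tagID"]),
        timestamp=ts,
        success=bool(obj.get("success", False)),
        coords=tuple(float(c) for c in coords),
        accel=tuple(float(a) for a in accel),
        status=int(tag_data.get("status", 0)),
        zones=zones,
    )


def read_pozyx_log(path) -> tuple[list[IndoorSample], DropReport]:
    """Read a JSON-lines indoor tag log into cleaned samples plus a drop report.

    Messages whose position could not be measured (``success: false``) are
    excluded from the positional output but counted in ``report.dropped``;
    unparseable lines are logged and counted in ``report.skipped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = DropReport()
    samples: list[IndoorSample] = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        report.total_lines += 1
        try:
            sample = _parse_pozyx_message(json.loads(line))
        except (json.JSONDecodeError, KeyError, TypeError, ValueError,
                MalformedRecordError) as e:
            logger.warning("skipping unparseable indoor line (%s): %.60s", e, line)
            report.skipped += 1
            continue
        if not sample.success:
            report.dropped += 1
            continue
        samples.append(sample)
        report.parsed += 1
    return samples, report


MISSING_TOKEN = "NA"


def write_feature_table(rows: pd.DataFrame | Sequence[dict], path) -> None:
    """Write a feature table as CSV with header; numeric round-trip at 1e-9.

    Missing categoricals are written as an explicit ``NA`` token so the file
    re-reads identically. Rows must share one column set.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            cols = set(rows[0].keys())
            for r in rows[1:]:
                if set(r.keys()) != cols:
                    raise ValueError("heterogeneous row columns in feature table")
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False, na_rep=MISSING_TOKEN, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    return pd.read_csv(path, na_values=[MISSING_TOKEN], keep_default_na=False)
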