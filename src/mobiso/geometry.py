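"""Coordinate conversions and distance/speed primitives.

Outdoor GPS fixes arrive as NMEA ddmm.mmmm strings; indoor UWB fixes are
already local Cartesian. Everything downstream (windowed mobility features,
place clustering) works in a local planar frame in metres, produced here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: International knot, exactly 1852 m per hour.
KNOT_MPS = 0.514444

#: Mean Earth radius in metres (spherical model).
EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class LocalPoint:
    """A position in a local planar frame, metres, with an epoch timestamp."""

    x: float
    y: float
    t: float
    z: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z, self.t):
            if not np.isfinite(v):
                raise ValueError("LocalPoint coordinates must be finite")


def nmea_to_decimal(raw: float | str, hemisphere: str) -> float:
    """Convert an NMEA ddmm.mmmm (lat) / dddmm.mmmm (lon) value to decimal degrees.

    The whole-degree part is everything left of the minutes field; minutes are
    divided by 60. Southern and western hemispheres are negative.

    Parameters
    ----------
    raw:
        Non-negative NMEA coordinate, e.g. ``6128.2257`` for 61° 28.2257'.
    hemisphere:
        One of ``N``, ``S``, ``E``, ``W``.
    """
    hemisphere = str(hemisphere).strip().upper()
    if hemisphere not in {"N", "S", "E", "W"}:
        raise ValueError(f"invalid hemisphere {hemisphere!r}")
    raw = float(raw)
    if raw < 0:
        raise ValueError("NMEA coordinate must be non-negative")
    degrees = np.floor(raw / 100.0)
    minutes = raw - 100.0 * degrees
    if minutes >= 60.0:
        raise ValueError(f"minutes field {minutes:.4f} out of range [0, 60)")
    value = degrees + minutes / 60.0
    if hemisphere in {"S", "W"}:
        value = -value
    limit = 90.0 if hemisphere in {"N", "S"} else 180.0
    if abs(value) > limit:
        raise ValueError(f"{value}° exceeds ±{limit}° for hemisphere {hemisphere}")
    return value


def to_local_xy(
    lat: float,
    lon: float,
    ref: tuple[float, float],
    t: float = 0.0,
) -> LocalPoint:
    """Project geographic coordinates to a local planar frame about ``ref``.

    Equirectangular projection with mid-latitude scaling: x is easting
    (longitude difference scaled by the cosine of the mean of the point's
    and the reference latitude), y is northing; ``ref`` maps to (0, 0).
    Within ~50 km of the reference the planar distance differs from the
    great-circle distance by < 0.1%, ample for city-scale mobility traces.
    """
    ref_lat, ref_lon = ref
    for name, v, lim in (("lat", lat, 90.0), ("ref lat", ref_lat, 90.0),
                         ("lon", lon, 180.0), ("ref lon", ref_lon, 180.0)):
        if abs(v) > lim:
            raise ValueError(f"{name} {v} outside ±{lim}°")
    mid_lat = 0.5 * (lat + ref_lat)
    x = np.radians(lon - ref_lon) * EARTH_RADIUS_M * np.cos(np.radians(mid_lat))
    y = np.radians(lat - ref_lat) * EARTH_RADIUS_M
    return LocalPoint(x=float(x), y=float(y), t=t)


def path_distance(points: Sequence[LocalPoint] | np.ndarray, use_z: bool = False) -> float:
    """Total polyline length: sum of consecutive Euclidean segment lengths.

    Accepts a sequence of :class:`LocalPoint` or an (n, 2+) coordinate array.
    Fewer than two points travel zero distance. Indoor tags may carry a z
    coordinate; it is ignored unless ``use_z`` is set.
    """
    if len(points) < 2:
        return 0.0
    if isinstance(points, np.ndarray):
        xy = np.asarray(points, dtype=float)
    else:
        dims = ("x", "y", "z") if use_z else ("x", "y")
        xy = np.array([[getattr(p, d) for d in dims] for p in points], dtype=float)
        use_z = False  # already sliced
    if not use_z and xy.shape[1] > 2 and not isinstance(points, np.ndarray):
        xy = xy[:, :2]
    segs = np.diff(xy, axis=0)
    return float(np.sum(np.linalg.norm(segs, axis=1)))


def estimated_speed(distance: float, dt: float) -> float:
    """Average speed in m/s over an interval: ``distance / dt``; dt must be > 0."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return float(distance) / float(dt)


def knots_to_mps(v: float) -> float:
    """Convert speed over ground from knots to m/s (× 0.514444)."""
    if v < 0:
        raise ValueError(f"speed in knots must be non-negative, got {v}")
    return float(v) * KNOT_MPS


def decimal_to_nmea(deg: float, is_lat: bool) -> tuple[str, str]:
    """Inverse of :func:`nmea_to_decimal`: decimal degrees → (ddmm.mmmm, hemisphere).

    Latitude uses 2 degree digits, longitude 3; minutes keep 4 decimals, the
    precision of the sentence format (≈ 0.2 m on the ground).
    """
    if is_lat:
        hemi = "N" if deg >= 0 else "S"
        if abs(deg) > 90:
            raise ValueError("latitude outside ±90°")
        width = 2
    else:
        hemi = "E" if deg >= 0 else "W"
        if abs(deg) > 180:
            raise ValueError("longitude outside ±180°")
        width = 3
    mag = abs(deg)
    d = int(mag)
    minutes = (mag - d) * 60.0
    if round(minutes, 4) >= 60.0:  # carry from rounding, e.g. 59.99997'
        d += 1
        minutes = 0.0
    return f"{d:0{width}d}{minutes:07.4f}", hemi
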