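"""Whale localisation: visual sightings, sonobuoy cross-bearing fixes, geodesy, solar altitude.

Visual observers log each sighting as a range and an angle relative to the
ship's course; paired DIFAR sonobuoys yield two simultaneous magnetic-corrected
true bearings to a calling whale.  Both are converted here into timestamped
whale positions on a spherical earth (mean radius 6371.0088 km).  At the 12-40 km
association scales used downstream, spherical geodesy is accurate to a few
metres, far below observational error.

Solar altitude (a low-precision NOAA-style ephemeris, good to ~0.1 deg) provides
the day/night annotation used by the effort simulator and reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6_371_008.8  # mean earth radius

__all__ = [
    "Sighting",
    "BearingPair",
    "WhaleDetection",
    "great_circle_distance",
    "destination_point",
    "initial_bearing",
    "sighting_position",
    "triangulate",
    "TriangulationFailure",
    "solar_altitude",
    "detections_frame",
]


@dataclass(frozen=True)
class Sighting:
    """A visual whale sighting from the ship.

    ``relative_angle`` is measured clockwise from the ship's head;
    the true bearing to the whale is ``(heading + relative_angle) % 360``.
    """

    time: pd.Timestamp
    ship_lat: float
    ship_lon: float
    ship_heading: float
    relative_angle: float
    range_m: float
    species: str = "blue_whale"

    def __post_init__(self):
        if not self.range_m > 0:
            raise ValueError("sighting range must be positive (range-less sightings are excluded upstream)")


@dataclass(frozen=True)
class BearingPair:
    """Simultaneous true bearings to one call from two sonobuoys."""

    time: pd.Timestamp
    lat_a: float
    lon_a: float
    bearing_a: float
    lat_b: float
    lon_b: float
    bearing_b: float

    def __post_init__(self):
        if self.lat_a == self.lat_b and self.lon_a == self.lon_b:
            raise ValueError("sonobuoys must be at distinct positions")


@dataclass(frozen=True)
class WhaleDetection:
    """A timestamped whale position from either observation system.

    ``quality`` is the range to the ship (m) for visual detections and the
    bearing-intersection angle (deg) for acoustic triangulations.
    """

    time: pd.Timestamp
    lat: float
    lon: float
    source: str  # "visual" | "acoustic"
    quality: float


class TriangulationFailure(Exception):
    """Raised when a bearing pair does not yield a usable cross fix."""


def great_circle_distance(lat1, lon1, lat2, lon2) -> float:
    """Haversine distance in metres; accepts scalars or arrays."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def destination_point(lat, lon, bearing_deg, distance_m):
    """Spherical direct problem: point at given initial bearing and distance."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_m, dtype=float) / EARTH_RADIUS_M
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(brg))
    lon2 = lon1 + np.arctan2(
        np.sin(brg) * np.sin(delta) * np.cos(lat1),
        np.cos(delta) - np.sin(lat1) * np.sin(lat2),
    )
    out_lat = np.degrees(lat2)
    out_lon = (np.degrees(lon2) + 540.0) % 360.0 - 180.0
    if np.ndim(out_lat) == 0:
        return float(out_lat), float(out_lon)
    return out_lat, out_lon


def initial_bearing(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, deg true in [0, 360)."""
    p1 = np.radians(np.asarray(lat1, dtype=float))
    p2 = np.radians(np.asarray(lat2, dtype=float))
    dlon = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    y = np.sin(dlon) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlon)
    b = (np.degrees(np.arctan2(y, x)) + 360.0) % 360.0
    return float(b) if np.ndim(b) == 0 else b


def sighting_position(s: Sighting) -> WhaleDetection:
    """Convert a visual sighting into a whale position.

    The whale lies at the sighting range along the true bearing
    ``(heading + relative angle) mod 360`` from the ship.
    """
    bearing = (s.ship_heading + s.relative_angle) % 360.0
    lat, lon = destination_point(s.ship_lat, s.ship_lon, bearing, s.range_m)
    return WhaleDetection(time=s.time, lat=lat, lon=lon, source="visual", quality=s.range_m)


# -- gnomonic projection helpers -------------------------------------------
# Great circles are straight lines in a gnomonic projection, so intersecting
# two bearing rays reduces to an exact 2-D line intersection.

def _gnomonic_forward(lat, lon, lat0, lon0):
    lat, lon, lat0, lon0 = (math.radians(v) for v in (lat, lon, lat0, lon0))
    cosc = math.sin(lat0) * math.sin(lat) + math.cos(lat0) * math.cos(lat) * math.cos(lon - lon0)
    if cosc <= 0:
        raise TriangulationFailure("point beyond the projection hemisphere")
    x = math.cos(lat) * math.sin(lon - lon0) / cosc
    y = (math.cos(lat0) * math.sin(lat) - math.sin(lat0) * math.cos(lat) * math.cos(lon - lon0)) / cosc
    return x, y


def _gnomonic_inverse(x, y, lat0, lon0):
    lat0r, lon0r = math.radians(lat0), math.radians(lon0)
    rho = math.hypot(x, y)
    if rho == 0:
        return lat0, lon0
    c = math.atan(rho)
    lat = math.asin(math.cos(c) * math.sin(lat0r) + y * math.sin(c) * math.cos(lat0r) / rho)
    lon = lon0r + math.atan2(
        x * math.sin(c), rho * math.cos(lat0r) * math.cos(c) - y * math.sin(lat0r) * math.sin(c)
    )
    return math.degrees(lat), (math.degrees(lon) + 540.0) % 360.0 - 180.0


def triangulate(
    pair: BearingPair,
    min_angle_deg: float = 10.0,
    max_range_m: float = 200_000.0,
) -> WhaleDetection:
    """Cross-bearing fix from two sonobuoys.

    The two bearing rays are intersected in a gnomonic plane centred midway
    between the buoys; each ray is the image of the great circle leaving the
    buoy at its bearing, which is exactly straight in this projection.

    Raises :class:`TriangulationFailure` for (anti)parallel bearings
    (intersection angle below ``min_angle_deg`` or above its supplement
    complementary gate), an intersection behind either bearing ray, or a fix
    beyond ``max_range_m`` from both buoys.
    """
    lat0 = 0.5 * (pair.lat_a + pair.lat_b)
    # handle dateline-spanning baselines
    dlon = ((pair.lon_b - pair.lon_a + 540.0) % 360.0) - 180.0
    lon0 = ((pair.lon_a + 0.5 * dlon + 540.0) % 360.0) - 180.0

    def ray(lat, lon, bearing):
        x0, y0 = _gnomonic_forward(lat, lon, lat0, lon0)
        # a second point 1 km along the great circle fixes the line exactly
        lat1, lon1 = destination_point(lat, lon, bearing, 1_000.0)
        x1, y1 = _gnomonic_forward(lat1, lon1, lat0, lon0)
        return np.array([x0, y0]), np.array([x1 - x0, y1 - y0])

    pa, da = ray(pair.lat_a, pair.lon_a, pair.bearing_a)
    pb, db = ray(pair.lat_b, pair.lon_b, pair.bearing_b)

    cross = da[0] * db[1] - da[1] * db[0]
    norm = np.linalg.norm(da) * np.linalg.norm(db)
    sin_angle = abs(cross) / norm
    cos_angle = float(np.dot(da, db)) / norm
    angle = math.degrees(math.atan2(sin_angle, cos_angle))  # in [0, 180]
    if angle < min_angle_deg or angle > 180.0 - min_angle_deg:
        raise TriangulationFailure(
            f"bearing intersection angle {angle:.1f} deg outside usable range (parallel/antiparallel bearings)"
        )

    # solve pa + t*da = pb + u*db
    rhs = pb - pa
    t = (rhs[0] * db[1] - rhs[1] * db[0]) / cross
    u = (rhs[0] * da[1] - rhs[1] * da[0]) / cross
    if t < 0 or u < 0:
        raise TriangulationFailure("bearings intersect behind a sonobuoy (no forward cross fix)")

    xi, yi = pa + t * da
    lat, lon = _gnomonic_inverse(xi, yi, lat0, lon0)
    r_a = great_circle_distance(pair.lat_a, pair.lon_a, lat, lon)
    r_b = great_circle_distance(pair.lat_b, pair.lon_b, lat, lon)
    if min(r_a, r_b) > max_range_m:
        raise TriangulationFailure(f"fix {min(r_a, r_b) / 1000:.0f} km from both buoys exceeds max range")
    return WhaleDetection(time=pair.time, lat=lat, lon=lon, source="acoustic", quality=angle)


def solar_altitude(lat, lon, time) -> float:
    """Solar elevation angle (deg, no refraction) at a UTC time.

    Low-precision NOAA ephemeris: fractional-year expansion of declination and
    the equation of time, then the standard hour-angle formula.  Accurate to
    about 0.1 deg, ample for day/night classification (day iff altitude > 0).
    Accepts scalars or arrays (broadcast over positions/times).
    """
    if isinstance(time, pd.DatetimeIndex):
        t = time
        scalar = False
    elif np.ndim(time) == 0:
        t = pd.DatetimeIndex([pd.Timestamp(time)])
        scalar = np.ndim(lat) == 0
    else:
        t = pd.DatetimeIndex(pd.to_datetime(time))
        scalar = False
    lat_r = np.radians(np.asarray(lat, dtype=float))
    lon_a = np.asarray(lon, dtype=float)

    doy = t.dayofyear.to_numpy()
    hours = t.hour.to_numpy() + t.minute.to_numpy() / 60.0 + t.second.to_numpy() / 3600.0
    leap = np.array([366 if pd.Timestamp(y, 12, 31).dayofyear == 366 else 365 for y in t.year])
    gamma = 2.0 * np.pi / leap * (doy - 1 + (hours - 12) / 24.0)

    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    tst = hours * 60.0 + eqtime + 4.0 * lon_a  # true solar time, minutes
    ha = np.radians(tst / 4.0 - 180.0)  # hour angle
    sin_alt = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha)
    alt = np.degrees(np.arcsin(np.clip(sin_alt, -1.0, 1.0)))
    return float(alt[0]) if scalar and alt.size == 1 else alt


def detections_frame(detections: list[WhaleDetection]) -> pd.DataFrame:
    """Tabulate detections (time, lat, lon, source, quality)."""
    return pd.DataFrame(
        {
            "time": [d.time for d in detections],
            "lat": [d.lat for d in detections],
            "lon": [d.lon for d in detections],
            "source": [d.source for d in detections],
            "quality": [d.quality for d in detections],
        }
    )
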