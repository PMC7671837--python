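"""GPS mobility features: stay points, places, visits, and the daily
mobility variables (new places, dwell time, distance, uncommon places,
route dissimilarity, timing shift, data coverage).

These features feed the social-opportunity variable (new places and the
time spent in them) and the variety variable (uncommon places, distance
travelled, routes taken, and the order/timing of visits) of the behaviour
engine. A "place" is operationalised with standard mobility-mining
parameters: stay points at 100 m radius / 10 min dwell, merged into places
at 150 m. All three radii are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from typing import Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

DEFAULT_STAY_RADIUS_M = 100.0
DEFAULT_MIN_DWELL_MIN = 10.0
DEFAULT_MERGE_RADIUS_M = 150.0
MAX_SPEED_KMH = 200.0           # jumps implying faster travel are GPS noise
UNCOMMON_MAX_VISITS = 2         # rolling-window visit count for "uncommon"
UNCOMMON_WINDOW_DAYS = 28
COVERAGE_SLOT_MIN = 30


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (vectorised)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def read_gps_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return _validate_fixes(df)


def read_gpx(path) -> pd.DataFrame:
    """Read track points (trkpt lat/lon/time) from a GPX 1.1 file."""
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = {"g": root.nsmap.get(None, "http://www.topografix.com/GPX/1/1")}
    rows = []
    for pt in root.findall(".//g:trkpt", ns):
        t = pt.find("g:time", ns)
        rows.append(
            {
                "timestamp": pd.Timestamp(t.text) if t is not None else pd.NaT,
                "lat": float(pt.get("lat")),
                "lon": float(pt.get("lon")),
            }
        )
    df = pd.DataFrame(rows, columns=["timestamp", "lat", "lon"])
    if len(df):
        df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.tz_localize(None)
    return _validate_fixes(df)


def _validate_fixes(df: pd.DataFrame) -> pd.DataFrame:
    if len(df) == 0:
        return df
    if df["lat"].abs().max() > 90 or df["lon"].abs().max() > 180:
        raise ValueError("latitude/longitude out of range")
    if not df["timestamp"].is_monotonic_increasing:
        raise ValueError("GPS timestamps must be non-decreasing")
    return df


@dataclass(frozen=True)
class StayPoint:
    lat: float
    lon: float
    arrival: pd.Timestamp
    departure: pd.Timestamp

    @property
    def dwell_min(self) -> float:
        return (self.departure - self.arrival) / pd.Timedelta(minutes=1)


@dataclass
class Place:
    place_id: int
    centroid_lat: float
    centroid_lon: float
    first_seen: Date
    visit_count: int = 0
    visit_dates: list = field(default_factory=list)


@dataclass(frozen=True)
class Visit:
    place_id: int
    arrival: pd.Timestamp
    departure: pd.Timestamp
    is_new_place: bool

    @property
    def dwell_min(self) -> float:
        return (self.departure - self.arrival) / pd.Timedelta(minutes=1)


def detect_stay_points(
    fixes: pd.DataFrame,
    radius_m: float = DEFAULT_STAY_RADIUS_M,
    min_dwell_min: float = DEFAULT_MIN_DWELL_MIN,
) -> list[StayPoint]:
    """Anchor-based stay-point extraction.

    A maximal subsequence of fixes all within `radius_m` of its first fix
    (the anchor) whose time span reaches `min_dwell_min` becomes a stay
    point at the centroid of its fixes. Fewer than 2 fixes yield no stay
    points.
    """
    n = len(fixes)
    if n < 2:
        return []
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    ts = pd.DatetimeIndex(fixes["timestamp"])
    out: list[StayPoint] = []
    i = 0
    while i < n - 1:
        d = haversine_km(lat[i], lon[i], lat[i + 1 :], lon[i + 1 :]) * 1000.0
        beyond = np.nonzero(d > radius_m)[0]
        j = (i + 1 + beyond[0]) if len(beyond) else n  # first fix outside
        span_min = (ts[j - 1] - ts[i]) / pd.Timedelta(minutes=1)
        if span_min >= min_dwell_min:
            out.append(
                StayPoint(
                    lat=float(lat[i:j].mean()),
                    lon=float(lon[i:j].mean()),
                    arrival=ts[i],
                    departure=ts[j - 1],
                )
            )
            i = j
        else:
            i += 1
    return out


class PlaceRegistry:
    """Running registry of known places with deterministic integer ids."""

    def __init__(self, merge_radius_m: float = DEFAULT_MERGE_RADIUS_M):
        self.merge_radius_m = merge_radius_m
        self.places: list[Place] = []

    def match(self, lat: float, lon: float) -> Place | None:
        if not self.places:
            return None
        plat = np.array([p.centroid_lat for p in self.places])
        plon = np.array([p.centroid_lon for p in self.places])
        d = haversine_km(lat, lon, plat, plon) * 1000.0
        k = int(np.argmin(d))
        return self.places[k] if d[k] <= self.merge_radius_m else None

    def visit_count_within(self, place: Place, day: Date, window_days: int) -> int:
        from datetime import timedelta

        lo = day - timedelta(days=window_days)
        return sum(1 for d in place.visit_dates if lo < d <= day)


def assign_places(
    stay_points: Sequence[StayPoint],
    registry: PlaceRegistry,
    day: Date,
) -> list[Visit]:
    """Match stay points to the registry (creating places as needed).

    A place is "new" on `day` iff this is the first day it was ever seen.
    The registry is updated in place; re-processing an identical fix stream
    against a fresh registry reproduces identical ids and visits.
    """
    visits: list[Visit] = []
    for sp in stay_points:
        place = registry.match(sp.lat, sp.lon)
        if place is None:
            place = Place(
                place_id=len(registry.places),
                centroid_lat=sp.lat,
                centroid_lon=sp.lon,
                first_seen=day,
            )
            registry.places.append(place)
        place.visit_count += 1
        place.visit_dates.append(day)
        visits.append(
            Visit(
                place_id=place.place_id,
                arrival=sp.arrival,
                departure=sp.departure,
                is_new_place=(place.first_seen == day),
            )
        )
    return visits


def daily_distance(
    fixes: pd.DataFrame, max_speed_kmh: float = MAX_SPEED_KMH
) -> float:
    """Distance travelled (km): summed consecutive-fix great-circle hops,
    discarding hops whose implied speed exceeds `max_speed_kmh` (GPS
    teleport artifacts)."""
    if len(fixes) < 2:
        return 0.0
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    ts = pd.DatetimeIndex(fixes["timestamp"]).asi8 / 1e9  # seconds
    d = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dt_h = np.diff(ts) / 3600.0
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.where(dt_h > 0, d / dt_h, np.inf)
    return float(d[(speed <= max_speed_kmh)].sum())


def _levenshtein(a: Sequence, b: Sequence) -> int:
    """Edit distance between two id sequences (tiny inputs; plain DP)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[-1]


def route_dissimilarity(
    today_visits: Sequence[Visit],
    baseline_day_visits: Sequence[Sequence[Visit]],
) -> tuple[float, float]:
    """How much today's routine differs from the closest baseline day.

    Returns ``(route_dissimilarity, timing_shift)``, both in [0, 1]:

    * route dissimilarity — normalised edit distance between today's ordered
      place-id sequence and each baseline day's sequence, minimised over
      baseline days (0 = identical to some routine day);
    * timing shift — for the best-matching baseline day, mean absolute
      difference between matched (position-paired) visit start times, scaled
      by 12 h and clamped to [0, 1].
    """
    if not baseline_day_visits:
        raise ValueError("empty baseline: no routine days to compare against")
    seq = [v.place_id for v in today_visits]
    best = (1.0, 1.0)
    for day_visits in baseline_day_visits:
        ref = [v.place_id for v in day_visits]
        denom = max(len(seq), len(ref))
        dist = _levenshtein(seq, ref) / denom if denom else 0.0
        if dist < best[0]:
            best = (dist, _timing_shift(today_visits, day_visits))
    return best


def _minutes_of_day(ts: pd.Timestamp) -> float:
    return ts.hour * 60 + ts.minute + ts.second / 60.0


def _timing_shift(today: Sequence[Visit], ref: Sequence[Visit]) -> float:
    pairs = list(zip(today, ref))
    if not pairs:
        return 0.0
    diffs = [
        abs(_minutes_of_day(a.arrival) - _minutes_of_day(b.arrival))
        for a, b in pairs
    ]
    return float(min(1.0, np.mean(diffs) / (12 * 60.0)))


def daily_coverage(
    fix_times: Sequence[pd.Timestamp],
    wear_minute_times: Sequence[pd.Timestamp],
    day: Date,
) -> float:
    """Fraction of the day's 48 half-hour slots containing at least one GPS
    fix or one wear minute of activity data."""
    slots = np.zeros(24 * 60 // COVERAGE_SLOT_MIN, dtype=bool)
    for ts in list(fix_times) + list(wear_minute_times):
        ts = pd.Timestamp(ts)
        if ts.date() == day:
            slots[(ts.hour * 60 + ts.minute) // COVERAGE_SLOT_MIN] = True
    return float(slots.mean())


def places_to_json(registry: PlaceRegistry, visits: Sequence[Visit] = ()) -> dict:
    """JSON-serialisable dump of the place registry (and optionally visits)
    for inspection."""
    return {
        "merge_radius_m": registry.merge_radius_m,
        "places": [
            {
                "place_id": p.place_id,
                "centroid_lat": p.centroid_lat,
                "centroid_lon": p.centroid_lon,
                "first_seen": p.first_seen.isoformat(),
                "visit_count": p.visit_count,
            }
            for p in registry.places
        ],
        "visits": [
            {
                "place_id": v.place_id,
                "arrival": v.arrival.isoformat(),
                "departure": v.departure.isoformat(),
                "is_new_place": v.is_new_place,
            }
            for v in visits
        ],
    }


@dataclass
class DailyMobility:
    date: Date
    n_new_places: int
    dwell_in_new_places_min: float
    distance_km: float
    n_uncommon_places: int
    route_dissimilarity: float
    timing_shift: float
    coverage: float


def daily_mobility(
    day: Date,
    fixes: pd.DataFrame,
    registry: PlaceRegistry,
    baseline_day_visits: Sequence[Sequence[Visit]] | None,
    wear_minute_times: Sequence[pd.Timestamp] = (),
    stay_radius_m: float = DEFAULT_STAY_RADIUS_M,
    min_dwell_min: float = DEFAULT_MIN_DWELL_MIN,
) -> tuple[DailyMobility, list[Visit]]:
    """One day of mobility features from raw fixes.

    Uncommon places are those visited today whose visit count over the
    trailing 28 days (including today) is at most 2. Route dissimilarity
    and timing shift are 0 when no baseline profile exists yet (the
    profiling week itself).
    """
    stay_points = detect_stay_points(fixes, stay_radius_m, min_dwell_min)
    visits = assign_places(stay_points, registry, day)
    new_visits = [v for v in visits if v.is_new_place]
    n_uncommon = 0
    for pid in {v.place_id for v in visits}:
        place = registry.places[pid]
        if (
            registry.visit_count_within(place, day, UNCOMMON_WINDOW_DAYS)
            <= UNCOMMON_MAX_VISITS
        ):
            n_uncommon += 1
    if baseline_day_visits:
        dissim, tshift = route_dissimilarity(visits, baseline_day_visits)
    else:
        dissim, tshift = 0.0, 0.0
    feats = DailyMobility(
        date=day,
        n_new_places=len({v.place_id for v in new_visits}),
        dwell_in_new_places_min=float(sum(v.dwell_min for v in new_visits)),
        distance_km=daily_distance(fixes),
        n_uncommon_places=n_uncommon,
        route_dissimilarity=dissim,
        timing_shift=tshift,
        coverage=daily_coverage(
            list(fixes["timestamp"]) if len(fixes) else [],
            wear_minute_times,
            day,
        ),
    )
    return feats, visits
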