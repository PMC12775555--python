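"""Migration and breeding phenology from GPS tracks.

A fix is "flying" at ground speed >= 15 km/h (derived from consecutive
positions when no speed is recorded). Stopover visits are the first and
last calendar day with a non-flying fix within the site radius. Arrival in
a breeding area is the first day a fix lies strictly beyond the area's
latitude (Svalbard) or longitude (Novaya Zemlya) boundary.

Nests are found from attendance: the candidate nest is the median
coordinate of "sitting still" fixes on days when the bird was mostly
sitting still; a nest is accepted when daily attendance (fraction of the
day's fixes within the attendance radius of the candidate) exceeds 75% for
at least 3 consecutive days. Laying is the first day of that run, the run
ends the first day attendance drops to 75% or below, and the nest is
successful — at least one egg hatched — when the run lasts 28-35 days, in
which case hatch is the last run day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .geo import haversine_km
from .onset import SpringOnsetRecord


@dataclass
class StopoverSite:
    site_id: str
    lat: float
    lon: float
    radius_km: float = 75.0

    def __post_init__(self):
        if not 50.0 <= self.radius_km <= 100.0:
            raise ValueError("stopover radius outside the 50-100 km band")


@dataclass
class VisitRecord:
    animal_id: str
    site_id: str
    year: int
    arrival_day: int
    departure_day: int

    def __post_init__(self):
        if self.arrival_day > self.departure_day:
            raise ValueError("visit arrival after departure")


@dataclass
class NestRecord:
    animal_id: str
    year: int
    lat: float
    lon: float
    laying_day: int
    run_length_days: int
    success: bool
    hatch_day: int | None
    attendance: dict = field(default_factory=dict)   # day_of_year -> fraction


@dataclass
class BreedingSummary:
    animal_id: str
    year: int
    breeding_area: str                 # "traditional" | "new"
    arrival_day: int | None
    attempted: bool
    laying_day: int | None = None
    success: bool | None = None
    pre_laying_interval_days: int | None = None
    brood_survived: bool | None = None

    def __post_init__(self):
        if not self.attempted and self.laying_day is not None:
            raise ValueError("laying fields must be absent when no attempt was made")


def _prepare(track: pd.DataFrame) -> pd.DataFrame:
    t = track.copy()
    t["timestamp"] = pd.to_datetime(t["timestamp"])
    t = t.sort_values("timestamp").reset_index(drop=True)
    if t["timestamp"].duplicated().any():
        raise ValueError("duplicate timestamps in track")
    t["day_of_year"] = t["timestamp"].dt.dayofyear
    t["year"] = t["timestamp"].dt.year
    return t


def flying_mask(track: pd.DataFrame, flight_speed_kmh: float = 15.0) -> np.ndarray:
    """True where the fix is in flight (speed >= threshold).

    Missing speeds are derived as great-circle distance / time to the
    previous fix; the first fix without a speed is left NaN and excluded
    from stationarity by the callers.
    """
    speed = track["ground_speed"].to_numpy(dtype=float) if "ground_speed" in track else np.full(len(track), np.nan)
    need = ~np.isfinite(speed)
    if need.any():
        lat = track["lat"].to_numpy(dtype=float)
        lon = track["lon"].to_numpy(dtype=float)
        ts = pd.to_datetime(track["timestamp"]).astype("int64").to_numpy() / 3.6e12  # hours
        d = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
        dt = np.diff(ts)
        derived = np.full(len(track), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            derived[1:] = np.where(dt > 0, d / dt, np.nan)
        speed = np.where(need, derived, speed)
    return speed >= flight_speed_kmh


def is_flying(fix: pd.Series, prev_fix: pd.Series | None = None, flight_speed_kmh: float = 15.0) -> bool:
    """Single-fix convenience wrapper around :func:`flying_mask`."""
    rows = [fix] if prev_fix is None else [prev_fix, fix]
    df = pd.DataFrame(rows)
    if "ground_speed" not in df:
        df["ground_speed"] = np.nan
    mask = flying_mask(df, flight_speed_kmh)
    sp = df["ground_speed"].iloc[-1]
    if not np.isfinite(sp) and prev_fix is None:
        raise ValueError("cannot classify: no speed and no previous fix")
    return bool(mask[-1])


def visit_dates(track: pd.DataFrame, site: StopoverSite, cfg: AnalysisConfig | None = None) -> VisitRecord | None:
    """First and last day with a non-flying fix within the site radius."""
    cfg = cfg or AnalysisConfig()
    t = _prepare(track)
    fly = flying_mask(t, cfg.flight_speed_kmh)
    dist = haversine_km(t["lat"].to_numpy(), t["lon"].to_numpy(), site.lat, site.lon)
    on_land = (~fly) & (dist <= site.radius_km)
    if not on_land.any():
        return None
    days = t.loc[on_land, "day_of_year"]
    return VisitRecord(
        animal_id=str(t["animal_id"].iloc[0]), site_id=site.site_id,
        year=int(t["year"].iloc[0]),
        arrival_day=int(days.min()), departure_day=int(days.max()),
    )


def breeding_arrival(track: pd.DataFrame, area: str, cfg: AnalysisConfig | None = None) -> int | None:
    """First day any fix passes the area boundary (strict inequality)."""
    cfg = cfg or AnalysisConfig()
    t = _prepare(track)
    if area == "svalbard":
        beyond = t["lat"].to_numpy() > cfg.svalbard_lat_boundary
    elif area == "novaya_zemlya":
        beyond = t["lon"].to_numpy() > cfg.novaya_zemlya_lon_boundary
    else:
        raise ValueError(f"unknown breeding area {area!r}")
    if not beyond.any():
        return None
    return int(t.loc[beyond, "day_of_year"].min())


def _still_cluster(still: pd.DataFrame, radius_m: float) -> pd.DataFrame:
    """Fixes belonging to the day's densest stationary cluster.

    The reference point is the non-flying fix with the most neighbours
    within the stationarity radius (a medoid); this stays on the nest even
    when nest and foraging fixes split the day evenly, where a raw
    component-wise median would land between the clusters.
    """
    lat = still["lat"].to_numpy(dtype=float)
    lon = still["lon"].to_numpy(dtype=float)
    n = len(still)
    counts = np.empty(n, dtype=int)
    for i in range(n):
        d = haversine_km(lat[i], lon[i], lat, lon) * 1000.0
        counts[i] = int((d <= radius_m).sum())
    ref = int(np.argmax(counts))
    d_ref = haversine_km(lat[ref], lon[ref], lat, lon) * 1000.0
    return still[d_ref <= radius_m]


def daily_stationarity(track: pd.DataFrame, day: int, cfg: AnalysisConfig | None = None):
    """(fraction of stationary fixes, median stationary coordinate) for one day.

    Stationary = non-flying and within the stationarity radius of the
    day's densest sitting-still cluster. Days with fewer than
    ``min_daily_fixes`` fixes are excluded (returns None).
    """
    cfg = cfg or AnalysisConfig()
    t = _prepare(track)
    sub = t[t["day_of_year"] == day]
    if len(sub) < cfg.min_daily_fixes:
        return None
    fly = flying_mask(sub, cfg.flight_speed_kmh)
    still = sub[~fly]
    if len(still) == 0:
        return 0.0, (np.nan, np.nan)
    stat = _still_cluster(still, cfg.stationarity_radius_m)
    frac = len(stat) / len(sub)
    return frac, (float(stat["lat"].median()), float(stat["lon"].median()))


def _attendance_runs(att: pd.Series, threshold: float):
    """Maximal runs of consecutive days with attendance > threshold."""
    runs = []
    start = prev = None
    for day, frac in att.items():
        ok = frac > threshold
        if ok and start is not None and day == prev + 1:
            prev = day
        elif ok:
            if start is not None:
                runs.append((start, prev))
            start = prev = day
        else:
            if start is not None:
                runs.append((start, prev))
            start = prev = None
    if start is not None:
        runs.append((start, prev))
    return runs


def detect_nest(track: pd.DataFrame, cfg: AnalysisConfig | None = None) -> NestRecord | None:
    """Locate a nest from attendance and date the breeding attempt.

    Steps: (1) per day with enough fixes, find the median position of
    sitting-still fixes and the still fraction; (2) candidate nest = the
    component-wise median of still fixes pooled over mostly-still days;
    (3) daily attendance = fraction of the day's fixes within the
    attendance radius of the candidate; (4) accept the earliest run of
    >=3 consecutive days with attendance > 75%. Laying = first run day;
    success iff the run lasts 28-35 days; hatch = last run day of a
    successful nest. With several qualifying runs the earliest is kept
    (renesting is out of scope).
    """
    cfg = cfg or AnalysisConfig()
    t = _prepare(track)
    fly = flying_mask(t, cfg.flight_speed_kmh)
    t["_fly"] = fly

    still_parts = []
    counts = t.groupby("day_of_year").size()
    good_days = counts[counts >= cfg.min_daily_fixes].index
    for day, sub in t[t["day_of_year"].isin(good_days)].groupby("day_of_year"):
        still = sub[~sub["_fly"]]
        if len(still) == 0:
            continue
        stat = _still_cluster(still, cfg.stationarity_radius_m)
        if len(stat) / len(sub) > cfg.mostly_still_fraction:
            still_parts.append(stat)
    if not still_parts:
        return None
    pooled = pd.concat(still_parts)
    cand_lat = float(pooled["lat"].median())
    cand_lon = float(pooled["lon"].median())

    # attendance over the day's non-flying fixes: a commuting or passing
    # flight cannot dilute attendance at the nest
    att = {}
    for day, sub in t[t["day_of_year"].isin(good_days)].groupby("day_of_year"):
        ground = sub[~sub["_fly"]]
        if len(ground) == 0:
            continue
        dist_m = haversine_km(ground["lat"].to_numpy(), ground["lon"].to_numpy(), cand_lat, cand_lon) * 1000.0
        att[int(day)] = float((dist_m <= cfg.attendance_radius_m).mean())
    att = pd.Series(att).sort_index()

    for start, end in _attendance_runs(att, cfg.attendance_fraction):
        run_length = end - start + 1
        if run_length >= cfg.min_attendance_days:
            success = cfg.success_run_min_days <= run_length <= cfg.success_run_max_days
            return NestRecord(
                animal_id=str(t["animal_id"].iloc[0]), year=int(t["year"].iloc[0]),
                lat=cand_lat, lon=cand_lon,
                laying_day=int(start), run_length_days=int(run_length),
                success=bool(success), hatch_day=int(end) if success else None,
                attendance={int(d): float(v) for d, v in att.items()},
            )
    return None


def breeding_propensity(summaries: list[BreedingSummary], area: str | None = None) -> tuple[int, int, float]:
    """(attempted, total, proportion) of tracked geese attempting to nest."""
    pool = [s for s in summaries if area is None or s.breeding_area == area]
    if not pool:
        raise ValueError("no breeding summaries for propensity")
    k = sum(s.attempted for s in pool)
    return k, len(pool), k / len(pool)


def nesting_success(nests: list[NestRecord | BreedingSummary], area: str | None = None) -> tuple[int, int, float]:
    """(successful, detected, proportion) over detected nests."""
    pool = [n for n in nests
            if (area is None or getattr(n, "breeding_area", area) == area)
            and getattr(n, "success", None) is not None]
    if not pool:
        raise ValueError("no nests for success proportion")
    k = sum(bool(n.success) for n in pool)
    return k, len(pool), k / len(pool)


def pre_laying_interval(summary: BreedingSummary) -> int:
    """Days from breeding-area arrival to laying (same-year convention)."""
    if summary.arrival_day is None or summary.laying_day is None:
        raise ValueError("arrival and laying days required")
    if summary.laying_day < summary.arrival_day:
        raise ValueError("laying before arrival")
    return int(summary.laying_day - summary.arrival_day)


def relative_timing(event_day: float, onset: SpringOnsetRecord, year: int | None = None) -> float:
    """Event day minus local spring onset; positive = after spring onset."""
    if year is not None and onset.year != year:
        raise ValueError(f"event year {year} does not match onset year {onset.year}")
    if onset.day_of_year is None:
        raise ValueError("onset record has no day (qc != ok)")
    return float(event_day - onset.day_of_year)
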