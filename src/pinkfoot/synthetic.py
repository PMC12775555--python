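"""Synthetic flyway scenarios with recorded ground truth.

Every input the pipeline consumes — 6-hourly site temperatures, per-pixel
NDSI/NDVI observations, GPS tracks, neckband resightings, field counts,
capture biometrics and autumn juvenile proportions — can be generated here
with configurable true event days, so every downstream stage is testable
against known truth without any external data.

Design points:

* One global seed expands into independent per-entity substreams (keyed by
  stage, site/animal and year), so adding entities never perturbs the data
  of existing ones.
* Seasonal index curves are logistic, giving analytic truth: the NDSI
  curve crosses the snow threshold exactly at the pixel's true melt day,
  and the NDVI curve has its maximum slope exactly at the true green-up
  day.
* Migration legs are great-circle flights at a fixed 70 km/h — far above
  the 15 km/h flight classification cut — and residency is a slow local
  wander around the site centroid.
* Nest attendance is deterministic per day: on each incubation day exactly
  ``round(p * fixes_per_day)`` fixes sit on the nest. This keeps the daily
  attendance fraction pinned at the configured probability instead of
  letting binomial sampling break long runs by chance.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .geo import haversine_km, great_circle_interpolate, offset_point

FLIGHT_SPEED_KMH = 70.0          # inside the 60-80 km/h band; >> 15 km/h cut
ARRIVAL_HOUR = 3.0               # flights land at 03:00 of the arrival day
SITE_SCATTER_KM = 2.0            # radius of the daily foraging wander
FORAGE_MIN_KM = 0.3              # off-nest fixes stay at least this far out


# ---------------------------------------------------------------------------
# scenario description


@dataclass
class SiteSpec:
    site_id: str
    lat: float
    lon: float
    role: str                              # "winter" | "stopover" | "breeding"
    subareas: tuple[str, ...] = ()
    boundary: str | None = None            # "svalbard" | "novaya_zemlya" for breeding areas
    route: str | None = None               # "traditional" | "new"


@dataclass
class Stay:
    site_id: str
    arrival_day: int
    departure_day: int

    def __post_init__(self):
        if self.arrival_day > self.departure_day:
            raise ValueError("stay with arrival after departure")


@dataclass
class Itinerary:
    stays: list[Stay]
    breeds: bool = False
    laying_day: int | None = None
    attendance_prob: float = 0.9
    nest_days: int | None = None           # length of the >75% attendance run
    track_end_day: int | None = None

    def __post_init__(self):
        for a, b in zip(self.stays, self.stays[1:]):
            if b.arrival_day <= a.departure_day:
                raise ValueError("overlapping itinerary segments")

    @property
    def success(self) -> bool | None:
        if not self.breeds or self.nest_days is None:
            return None
        return 28 <= self.nest_days <= 35


@dataclass
class ScenarioConfig:
    seed: int
    years: list[int]
    sites: dict[str, SiteSpec]
    n_individuals: int
    fix_rate: int = 16                     # fixes per day
    gps_sd_m: float = 15.0
    index_sd: float = 0.02
    temp_sd_c: float = 0.0
    temp_ramp_c_per_day: float = 0.15
    temp_cap_c: float = 16.0
    pixel_truth_sd_days: float = 3.0
    index_missingness: float = 0.0
    # per (site_id, year): true event days {"gdd": d, "snowmelt": d, "greenup": d}
    onsets: dict = field(default_factory=dict)
    # per (animal_id, year)
    itineraries: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fix_rate < 1:
            raise ValueError("fix_rate must be >= 1")
        for (aid, yr), itin in self.itineraries.items():
            if itin.breeds and itin.success and not 20 <= itin.nest_days - 1 <= 45:
                raise ValueError(f"incubation length out of [20, 45] for {aid}/{yr}")


def _rng(seed: int, *key) -> np.random.Generator:
    """Independent substream for one entity; stable under scenario growth."""
    tag = zlib.crc32("|".join(str(k) for k in key).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _dates(year: int, fractional_days: np.ndarray) -> pd.DatetimeIndex:
    base = pd.Timestamp(year=year, month=1, day=1)
    return base + pd.to_timedelta((fractional_days - 1.0) * 24.0, unit="h")


# ---------------------------------------------------------------------------
# temperature


def gen_temperature_series(cfg: ScenarioConfig, site_id: str, year: int) -> pd.DataFrame:
    """6-hourly temperatures, 1 Jan-30 Sep, with the GDD acceleration at t0.

    Construction: daily mean 0 degC before the true onset day, then a linear
    ramp (capped) after it, so the cumulative-GDD curve switches from flat
    to quadratic exactly at t0. A diurnal cycle sampled at the quarter
    phases averages to zero and leaves daily means unchanged; Gaussian
    noise is added per 6-h value.
    """
    try:
        t0 = cfg.onsets[(site_id, year)]["gdd"]
    except KeyError:
        raise KeyError(f"no true onset for site {site_id!r}, year {year}") from None
    rng = _rng(cfg.seed, "temp", site_id, year)
    days = np.arange(1, 274)  # 1 Jan - 30 Sep
    daily_mean = np.minimum(np.maximum(0.0, (days - t0) * cfg.temp_ramp_c_per_day), cfg.temp_cap_c)
    hours = np.array([0.0, 6.0, 12.0, 18.0])
    diurnal = 3.0 * np.sin(2.0 * np.pi * hours / 24.0)  # sums to zero exactly
    temps = daily_mean[:, None] + diurnal[None, :]
    temps = temps + rng.normal(0.0, cfg.temp_sd_c, size=temps.shape)
    frac = days[:, None] + hours[None, :] / 24.0
    return pd.DataFrame({
        "site_id": site_id,
        "timestamp": _dates(year, frac.ravel()),
        "temp_c": temps.ravel(),
    })


# ---------------------------------------------------------------------------
# satellite indices


def _logistic(x, lo, hi, k, mid):
    return lo + (hi - lo) / (1.0 + np.exp(-k * (x - mid)))


# NDSI falls from snow-covered ~0.79 to bare ~0.05; the midpoint value
# (0.79 + 0.05) / 2 = 0.42 equals the snow threshold, so the curve crosses
# the threshold exactly at the logistic midpoint = the pixel's true melt day.
NDSI_HI, NDSI_LO, NDSI_K = 0.79, 0.05, 0.25
NDVI_LO, NDVI_HI, NDVI_K = 0.10, 0.80, 0.15


def gen_pixel_series(
    cfg: ScenarioConfig,
    site_id: str,
    year: int,
    kind: str,
    n_pixels: int,
    window: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pixel index observations every ~2 days, plus a pixel-truth table.

    NDSI declines through the snow threshold at each pixel's true melt day;
    NDVI rises with maximum slope at each pixel's true green-up day. Pixel
    truths scatter normally around the site truth. Missingness (cloud gaps)
    drops observations at the configured rate; values are clipped to [-1, 1].
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    if kind not in ("NDSI", "NDVI"):
        raise ValueError(f"unknown index kind {kind!r}")
    truth_key = "snowmelt" if kind == "NDSI" else "greenup"
    site_day = cfg.onsets[(site_id, year)][truth_key]
    site = cfg.sites[site_id]
    if window is None:
        window = (74, 258) if site.role == "breeding" else (1, 181)
    rng = _rng(cfg.seed, "pixel", site_id, year, kind)
    days = np.arange(window[0], window[1] + 1, 2, dtype=float)
    rows, truths = [], []
    for p in range(n_pixels):
        pid = f"{site_id}_px{p:03d}"
        pday = site_day + rng.normal(0.0, cfg.pixel_truth_sd_days)
        if kind == "NDSI":
            vals = _logistic(days, NDSI_HI, NDSI_LO, NDSI_K, pday)
        else:
            vals = _logistic(days, NDVI_LO, NDVI_HI, NDVI_K, pday)
        vals = vals + rng.normal(0.0, cfg.index_sd, size=vals.shape)
        keep = rng.random(len(days)) >= cfg.index_missingness
        rows.append(pd.DataFrame({
            "pixel_id": pid, "site_id": site_id, "kind": kind,
            "date": _dates(year, days[keep]).normalize(),
            "day_of_year": days[keep].astype(int),
            "value": np.clip(vals[keep], -1.0, 1.0),
        }))
        truths.append({"pixel_id": pid, "site_id": site_id, "year": year,
                       "kind": kind, "true_day": float(pday)})
    return pd.concat(rows, ignore_index=True), pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# GPS tracks


@dataclass
class TrackTruth:
    animal_id: str
    year: int
    site_arrival: dict            # site_id -> first day with a non-flying on-site fix
    site_departure: dict          # site_id -> last such day
    breeding_arrival_day: int | None
    breeds: bool
    laying_day: int | None
    hatch_day: int | None         # laying + incubation, successful nests only
    success: bool | None
    nest_lat: float | None
    nest_lon: float | None


def _wander(rng, lat, lon, n, scatter_km=SITE_SCATTER_KM, min_km=0.0):
    r = np.sqrt(rng.random(n)) * (scatter_km - min_km) + min_km
    theta = rng.random(n) * 2.0 * np.pi
    return offset_point(lat, lon, r * 1000.0 * np.cos(theta), r * 1000.0 * np.sin(theta))


def gen_track(cfg: ScenarioConfig, animal_id: str, year: int) -> tuple[pd.DataFrame, TrackTruth]:
    """Simulate one goose-year of GPS fixes and its ground truth.

    The bird sits at each itinerary site (slow local wander), flies
    great-circle legs at 70 km/h timed to land at 03:00 of the next
    arrival day, and — if breeding — holds a nest phase in which a fixed
    fraction of each day's fixes lies at the true nest coordinate.
    Truths (site arrival/departure days, breeding-area boundary crossing,
    laying/hatch/success) are derived from the noise-free planned path.
    """
    itin = cfg.itineraries[(animal_id, year)]
    rng = _rng(cfg.seed, "track", animal_id, year)
    fr = cfg.fix_rate

    start_day = itin.stays[0].arrival_day
    end_day = itin.track_end_day or (itin.stays[-1].departure_day)
    t = np.arange(start_day, end_day + 1, dtype=float)
    t = (t[:, None] + (np.arange(fr) + 0.5)[None, :] / fr).ravel()  # fix times, fractional days

    lat = np.empty_like(t)
    lon = np.empty_like(t)
    speed = np.empty_like(t)
    seg_of = np.full(len(t), -1)  # index of the stay each fix belongs to, -1 = in flight

    # flight schedule between consecutive stays
    bounds = []  # per stay: (occupied_from_time, occupied_until_time)
    occupied_from = float(start_day)
    for k, stay in enumerate(itin.stays):
        if k + 1 < len(itin.stays):
            nxt = itin.stays[k + 1]
            a, b = cfg.sites[stay.site_id], cfg.sites[nxt.site_id]
            dist = float(haversine_km(a.lat, a.lon, b.lat, b.lon))
            dur_days = dist / FLIGHT_SPEED_KMH / 24.0
            arr_time = nxt.arrival_day + ARRIVAL_HOUR / 24.0
            dep_time = arr_time - dur_days
            if dep_time <= max(occupied_from, stay.arrival_day):
                raise ValueError(f"overlapping itinerary segments for {animal_id}/{year} "
                                 f"({stay.site_id} -> {nxt.site_id})")
        else:
            dep_time = float(end_day + 1)
            arr_time = dep_time
        bounds.append((occupied_from, dep_time, arr_time))
        occupied_from = arr_time

    for k, stay in enumerate(itin.stays):
        t_from, t_dep, t_arr_next = bounds[k]
        on_site = (t >= t_from) & (t < t_dep)
        site = cfg.sites[stay.site_id]
        n = int(on_site.sum())
        la, lo = _wander(rng, site.lat, site.lon, n)
        lat[on_site], lon[on_site] = la, lo
        speed[on_site] = rng.uniform(0.0, 8.0, n)
        seg_of[on_site] = k
        if k + 1 < len(itin.stays):
            nxt_site = cfg.sites[itin.stays[k + 1].site_id]
            in_flight = (t >= t_dep) & (t < t_arr_next)
            frac = (t[in_flight] - t_dep) / (t_arr_next - t_dep)
            fla, flo = great_circle_interpolate(site.lat, site.lon, nxt_site.lat, nxt_site.lon, frac)
            lat[in_flight], lon[in_flight] = fla, flo
            speed[in_flight] = FLIGHT_SPEED_KMH

    # nest phase overrides the wander inside the breeding stay
    nest_lat = nest_lon = None
    hatch_day = None
    if itin.breeds:
        breeding_stays = [s for s in itin.stays if cfg.sites[s.site_id].role == "breeding"]
        if not breeding_stays:
            raise ValueError("breeds flag set but itinerary has no breeding stay")
        bsite = cfg.sites[breeding_stays[0].site_id]
        nest_lat, nest_lon = _wander(rng, bsite.lat, bsite.lon, 1, scatter_km=3.0)
        nest_lat, nest_lon = float(nest_lat[0]), float(nest_lon[0])
        n_on = int(round(itin.attendance_prob * fr))
        for d in range(itin.laying_day, itin.laying_day + itin.nest_days):
            day_mask = (t >= d) & (t < d + 1) & (seg_of >= 0)
            idx = np.flatnonzero(day_mask)
            if len(idx) == 0:
                continue
            on_nest = rng.permutation(idx)[: min(n_on, len(idx))]
            lat[on_nest], lon[on_nest] = nest_lat, nest_lon
            speed[on_nest] = rng.uniform(0.0, 1.0, len(on_nest))
            off_nest = np.setdiff1d(idx, on_nest)
            la, lo = _wander(rng, nest_lat, nest_lon, len(off_nest), min_km=FORAGE_MIN_KM)
            lat[off_nest], lon[off_nest] = la, lo
        if itin.success:
            hatch_day = itin.laying_day + (itin.nest_days - 1)

    # truths from the planned (noise-free) path
    day = np.floor(t).astype(int)
    site_arrival, site_departure = {}, {}
    for k, stay in enumerate(itin.stays):
        on = seg_of == k
        if on.any():
            site_arrival[stay.site_id] = int(day[on].min())
            site_departure[stay.site_id] = int(day[on].max())
    breeding_arrival_day = None
    for stay in itin.stays:
        site = cfg.sites[stay.site_id]
        if site.role == "breeding" and site.boundary is not None:
            crossed = lat > 76.5640 if site.boundary == "svalbard" else lon > 51.4432
            if crossed.any():
                breeding_arrival_day = int(day[np.argmax(crossed)])
            break

    # GPS noise on the emitted positions
    dx = rng.normal(0.0, cfg.gps_sd_m, len(t))
    dy = rng.normal(0.0, cfg.gps_sd_m, len(t))
    lat_out = lat + dy / 111_194.9
    lon_out = lon + dx / (111_194.9 * np.cos(np.radians(np.clip(lat, -89.0, 89.0))))

    fixes = pd.DataFrame({
        "animal_id": animal_id,
        "timestamp": _dates(year, t),
        "lat": lat_out,
        "lon": lon_out,
        "ground_speed": speed,
    })
    truth = TrackTruth(
        animal_id=animal_id, year=year,
        site_arrival=site_arrival, site_departure=site_departure,
        breeding_arrival_day=breeding_arrival_day,
        breeds=itin.breeds,
        laying_day=itin.laying_day if itin.breeds else None,
        hatch_day=hatch_day,
        success=itin.success,
        nest_lat=nest_lat, nest_lon=nest_lon,
    )
    return fixes, truth


# ---------------------------------------------------------------------------
# resightings and counts


def presence_interval(cfg: ScenarioConfig, animal_id: str, year: int, site_id: str) -> tuple[int, int] | None:
    itin = cfg.itineraries.get((animal_id, year))
    if itin is None:
        return None
    for stay in itin.stays:
        if stay.site_id == site_id:
            return stay.arrival_day, stay.departure_day
    return None


def gen_resightings(
    cfg: ScenarioConfig, site_id: str, year: int, detection_prob: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Neckband resightings: one Bernoulli(detection_prob) trial per bird-day.

    Returns (resightings, truth) where truth holds each bird's exact first
    and last presence day at the site.
    """
    if not 0.0 < detection_prob <= 1.0:
        raise ValueError("detection_prob must be in (0, 1]")
    rng = _rng(cfg.seed, "resight", site_id, year)
    rows, truths = [], []
    for (aid, yr), itin in sorted(cfg.itineraries.items()):
        if yr != year:
            continue
        iv = presence_interval(cfg, aid, yr, site_id)
        if iv is None:
            continue
        arr, dep = iv
        days = np.arange(arr, dep + 1)
        seen = days[rng.random(len(days)) < detection_prob]
        for d in seen:
            rows.append({"ring_id": aid, "site_id": site_id, "date": None, "day_of_year": int(d)})
        truths.append({"ring_id": aid, "site_id": site_id, "year": year,
                       "first_day": int(arr), "last_day": int(dep)})
    df = pd.DataFrame(rows, columns=["ring_id", "site_id", "date", "day_of_year"])
    if len(df):
        df["date"] = pd.to_datetime(f"{year}-01-01") + pd.to_timedelta(df["day_of_year"] - 1, unit="D")
    return df, pd.DataFrame(truths, columns=["ring_id", "site_id", "year", "first_day", "last_day"])


def gen_counts(
    cfg: ScenarioConfig, site_id: str, year: int,
    pop_scale: float = 50.0, interval_days: int = 2, count_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Field counts every ``interval_days``: birds present x pop_scale + noise."""
    rng = _rng(cfg.seed, "count", site_id, year)
    intervals = [presence_interval(cfg, aid, yr, site_id)
                 for (aid, yr) in cfg.itineraries if yr == year]
    intervals = [iv for iv in intervals if iv is not None]
    if not intervals:
        return pd.DataFrame(columns=["site_id", "date", "day_of_year", "count"])
    lo = min(a for a, _ in intervals) - 4
    hi = max(b for _, b in intervals) + 4
    days = np.arange(lo, hi + 1, interval_days)
    present = np.array([sum(a <= d <= b for a, b in intervals) for d in days], dtype=float)
    counts = np.maximum(0, np.round(present * pop_scale + rng.normal(0, count_noise_sd, len(days)))).astype(int)
    return pd.DataFrame({
        "site_id": site_id,
        "date": pd.to_datetime(f"{year}-01-01") + pd.to_timedelta(days - 1, unit="D"),
        "day_of_year": days,
        "count": counts,
    })


# ---------------------------------------------------------------------------
# captures / biometrics


DEFAULT_ALLOMETRY = {
    # sex -> (intercept g, slope g/mm, wing mean mm, wing sd mm, head mean mm, head sd mm)
    "M": (-1500.0, 10.0, 460.0, 12.0, 98.0, 3.0),
    "F": (-1400.0, 9.5, 440.0, 12.0, 93.0, 3.0),
}


def gen_captures(
    cfg: ScenarioConfig,
    route_effect_g: float | dict = 0.0,
    allometry: dict = None,
    n_captures: int = 400,
    mass_noise_sd: float = 0.0,
    years: list[int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Capture biometrics with a sex-specific mass-on-wing allometry.

    ``route_effect_g`` adds mass on the new route; a dict keyed by sex
    ("M"/"F") makes it sex-specific. Returns (captures, truth).
    """
    allometry = allometry or DEFAULT_ALLOMETRY
    years = years or cfg.years
    rng = _rng(cfg.seed, "captures")
    if not isinstance(route_effect_g, dict):
        route_effect_g = {"M": float(route_effect_g), "F": float(route_effect_g)}
    rows = []
    for i in range(n_captures):
        sex = "M" if rng.random() < 0.5 else "F"
        route = "traditional" if rng.random() < 0.5 else "new"
        site = "trondelag" if route == "traditional" else "oulu"
        a, b, wmu, wsd, hmu, hsd = allometry[sex]
        wing = round(float(np.clip(rng.normal(wmu, wsd), 360.0, 515.0)), 1)
        head = round(float(np.clip(rng.normal(hmu, hsd), 82.0, 118.0)), 1)
        mass = a + b * wing + (route_effect_g[sex] if route == "new" else 0.0)
        mass += rng.normal(0.0, mass_noise_sd)
        year = int(rng.choice(years))
        doy = int(rng.integers(114, 128))  # 24 Apr - 7 May
        rows.append({
            "animal_id": f"cap{i:04d}", "year": year, "day_of_year": doy,
            "date": pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=doy - 1),
            "site": site, "route": route, "sex": sex,
            "head_mm": round(head, 1), "wing_mm": round(wing, 1), "mass_g": float(mass),
        })
    truth = {"route_effect_g": route_effect_g,
             "allometry": {s: {"intercept": v[0], "slope": v[1]} for s, v in allometry.items()}}
    return pd.DataFrame(rows), truth


def gen_juvenile_table(
    cfg: ScenarioConfig,
    onset_by_year: dict[int, float],
    slope_per_day: float = -0.005,
    intercept: float = 1.0,
    noise_sd: float = 0.02,
    populations: tuple[str, ...] = ("traditional", "new"),
    population_effect: float = 0.0,
) -> pd.DataFrame:
    """Autumn juvenile proportions, linear in spring onset per population."""
    rng = _rng(cfg.seed, "juveniles")
    rows = []
    for pop in populations:
        for year, onset in sorted(onset_by_year.items()):
            prop = intercept + slope_per_day * onset + (population_effect if pop == "new" else 0.0)
            prop += rng.normal(0.0, noise_sd)
            rows.append({"population": pop, "year": year,
                         "onset_day": onset, "juvenile_proportion": float(np.clip(prop, 0.0, 1.0))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# default scenario factory


DEFAULT_SITES = {
    "winter_dk": SiteSpec("winter_dk", 56.0, 9.0, "winter"),
    "trondelag": SiteSpec("trondelag", 63.5, 10.5, "stopover", route="traditional"),
    "oulu": SiteSpec("oulu", 65.0, 25.5, "stopover", route="new"),
    "svalbard": SiteSpec("svalbard", 78.0, 16.0, "breeding",
                         subareas=tuple(f"sv{j}" for j in range(1, 7)),
                         boundary="svalbard", route="traditional"),
    "novaya_zemlya": SiteSpec("novaya_zemlya", 72.5, 55.0, "breeding",
                              subareas=tuple(f"nz{j}" for j in range(1, 7)),
                              boundary="novaya_zemlya", route="new"),
}


def default_scenario(
    seed: int,
    years: list[int] | None = None,
    n_individuals: int = 40,
    breeding_propensity: float = 0.6,
    success_prob: float = 0.5,
    attendance_prob: float = 0.9,
    gps_sd_m: float = 15.0,
    index_sd: float = 0.02,
    temp_sd_c: float = 1.5,
    index_missingness: float = 0.0,
) -> ScenarioConfig:
    """A two-route flyway: Denmark winter, Trondelag/Oulu stopovers,
    Svalbard / Novaya Zemlya breeding areas, with randomized true event days.

    Individuals split evenly between the routes. True spring-onset days
    drift earlier through the years (about -0.4 d/yr) around late-May
    breeding-area values, emulating an advancing Arctic spring.
    """
    years = years or [2019, 2020, 2021, 2022]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11CE]))
    cfg = ScenarioConfig(seed=seed, years=list(years), sites=dict(DEFAULT_SITES),
                         n_individuals=n_individuals, gps_sd_m=gps_sd_m,
                         index_sd=index_sd, temp_sd_c=temp_sd_c,
                         index_missingness=index_missingness)
    base = {"winter_dk": 60.0, "trondelag": 105.0, "oulu": 110.0,
            "svalbard": 145.0, "novaya_zemlya": 155.0}
    y0 = years[0]
    for site_id in cfg.sites:
        for year in years:
            mid = base[site_id] - 0.4 * (year - y0) + rng.normal(0.0, 4.0)
            cfg.onsets[(site_id, year)] = {
                "gdd": round(mid, 1),
                "snowmelt": round(mid + 5.0 + rng.normal(0.0, 2.0), 1),
                "greenup": round(mid + 12.0 + rng.normal(0.0, 2.0), 1),
            }
    for i in range(n_individuals):
        aid = f"goose{i:03d}"
        route = "traditional" if i % 2 == 0 else "new"
        stopover = "trondelag" if route == "traditional" else "oulu"
        breeding = "svalbard" if route == "traditional" else "novaya_zemlya"
        for year in years:
            dep_w = int(rng.integers(95, 106))
            arr_s = dep_w + 2
            dep_s = arr_s + int(rng.integers(15, 26))
            arr_b = dep_s + 3
            breeds = bool(rng.random() < breeding_propensity)
            laying = nest_days = None
            if breeds:
                laying = arr_b + int(rng.integers(5, 15))
                if rng.random() < success_prob:
                    nest_days = int(rng.integers(28, 36))
                else:
                    nest_days = int(rng.integers(4, 21))
            cfg.itineraries[(aid, year)] = Itinerary(
                stays=[Stay("winter_dk", 15, dep_w),
                       Stay(stopover, arr_s, dep_s),
                       Stay(breeding, arr_b, arr_b + 90)],
                breeds=breeds, laying_day=laying,
                attendance_prob=attendance_prob, nest_days=nest_days,
                track_end_day=arr_b + 90,
            )
    return cfg


# ---------------------------------------------------------------------------
# scenario output


def write_scenario(cfg: ScenarioConfig, out_dir: str | Path, n_pixels: int = 20,
                   detection_prob: float = 0.8) -> dict:
    """Generate every pipeline input for the scenario and write CSVs plus a
    JSON truth sidecar. Returns the truth dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    temps, pixels, tracks, resights, counts = [], [], [], [], []
    truth = {"onsets": {}, "animals": [], "presence": [], "pixels": []}
    for (site_id, year), days in sorted(cfg.onsets.items()):
        truth["onsets"][f"{site_id}:{year}"] = days
        temps.append(gen_temperature_series(cfg, site_id, year))
        site = cfg.sites[site_id]
        if site.role in ("stopover", "breeding"):
            for kind in ("NDSI", "NDVI"):
                px, pxt = gen_pixel_series(cfg, site_id, year, kind, n_pixels)
                pixels.append(px)
                truth["pixels"].extend(pxt.to_dict("records"))
    for (aid, year) in sorted(cfg.itineraries):
        fixes, tr = gen_track(cfg, aid, year)
        tracks.append(fixes)
        truth["animals"].append(asdict(tr))
    for site_id, site in cfg.sites.items():
        if site.role != "stopover":
            continue
        for year in cfg.years:
            rs, rst = gen_resightings(cfg, site_id, year, detection_prob)
            resights.append(rs)
            truth["presence"].extend(rst.to_dict("records"))
            counts.append(gen_counts(cfg, site_id, year))
    captures, cap_truth = gen_captures(cfg)
    truth["captures"] = cap_truth

    pd.concat(temps, ignore_index=True).to_csv(out / "temperature.csv", index=False)
    pd.concat(pixels, ignore_index=True).drop(columns=["day_of_year"]).to_csv(out / "pixel_index.csv", index=False)
    pd.concat(tracks, ignore_index=True).to_csv(out / "tracks.csv", index=False)
    pd.concat(resights, ignore_index=True).drop(columns=["day_of_year"]).to_csv(out / "resightings.csv", index=False)
    pd.concat(counts, ignore_index=True).drop(columns=["day_of_year"]).to_csv(out / "counts.csv", index=False)
    captures.drop(columns=["year", "day_of_year"]).to_csv(out / "captures.csv", index=False)
    sites_df = pd.DataFrame([{
        "site_id": s.site_id, "lat": s.lat, "lon": s.lon, "role": s.role,
        "boundary": s.boundary or "", "route": s.route or "",
    } for s in cfg.sites.values()])
    sites_df.to_csv(out / "sites.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return truth
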