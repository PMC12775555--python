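"""Spring-onset extraction from temperature and satellite-index series.

Three measures of the start of spring are computed per site (or breeding
subarea) and year:

* **gdd** — the day on which cumulative growing degree days accelerate
  fastest, operationalised as the maximum of the third discrete difference
  ("jerk") of the smoothed cumulative-GDD curve;
* **snowmelt** — per pixel, the first day the spline-smoothed NDSI drops
  below 0.42 after having been snow-covered; the site value is the pixel
  median (the day half the snow-covered area is snow-free);
* **greenup** — per pixel, the day of fastest NDVI increase on the smoothed
  curve; the site value is the pixel mean.

Per-pixel smoothing uses a penalized cubic smoothing spline with the
penalty chosen by generalized cross-validation (a fixed penalty can be
supplied for bit-reproducible runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .config import AnalysisConfig

_JERK_TOL = 1e-6  # below this, the GDD curve has no acceleration change


class Qc(str, Enum):
    OK = "ok"
    NO_EVENT = "no_event"
    INSUFFICIENT_DATA = "insufficient_data"
    EXCLUDED = "excluded"  # pixel-level only: e.g. never snow-covered


@dataclass
class GddCurve:
    site_id: str
    year: int
    day_of_year: np.ndarray      # integer days, starting 1 Jan
    cumulative_gdd: np.ndarray   # degC * day, non-negative, non-decreasing

    def __post_init__(self):
        self.day_of_year = np.asarray(self.day_of_year, dtype=int)
        self.cumulative_gdd = np.asarray(self.cumulative_gdd, dtype=float)
        if np.any(np.diff(self.cumulative_gdd) < -1e-12):
            raise ValueError("cumulative GDD must be non-decreasing")


@dataclass
class SmoothedIndexCurve:
    pixel_id: str
    kind: str                    # "NDSI" or "NDVI"
    day_of_year: np.ndarray      # daily grid over the window
    values: np.ndarray

    def __post_init__(self):
        self.day_of_year = np.asarray(self.day_of_year, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("smoothed curve contains non-finite values")


@dataclass
class SpringOnsetRecord:
    site_id: str
    year: int
    method: str                  # "gdd" | "snowmelt" | "greenup"
    day_of_year: float | None
    n_pixels_used: int = 0
    qc_flag: Qc = Qc.OK


def daily_mean_temperature(series: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of the 6-hourly temperatures per calendar day.

    ``series`` needs columns ``timestamp`` (datetime-like) and ``temp_c``.
    Returns a Series indexed by day of year over the observed span; days
    without any observation are NaN.
    """
    if len(series) == 0:
        raise ValueError("empty temperature series")
    ts = pd.to_datetime(series["timestamp"])
    doy = ts.dt.dayofyear
    daily = series.groupby(doy.values)["temp_c"].mean()
    full = pd.Series(np.nan, index=pd.RangeIndex(int(daily.index.min()), int(daily.index.max()) + 1))
    full.loc[daily.index] = daily.values
    full.index.name = "day_of_year"
    return full


def cumulative_gdd(
    daily: pd.Series,
    base_temp: float = 0.0,
    site_id: str = "",
    year: int = 0,
    max_missing_fraction: float = 0.2,
) -> GddCurve:
    """Accumulate max(0, T_day - base) from 1 January.

    Missing days contribute zero. The fraction of missing days must not
    exceed ``max_missing_fraction``.
    """
    if int(daily.index.min()) != 1:
        raise ValueError("daily series must start on 1 January (day 1)")
    vals = daily.to_numpy(dtype=float)
    n_missing = int(np.isnan(vals).sum())
    if n_missing > max_missing_fraction * len(vals):
        raise ValueError(f"{n_missing}/{len(vals)} days missing exceeds the allowed fraction")
    contrib = np.where(np.isnan(vals), 0.0, np.maximum(0.0, vals - base_temp))
    return GddCurve(site_id=site_id, year=year,
                    day_of_year=daily.index.to_numpy(), cumulative_gdd=np.cumsum(contrib))


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.astype(float)
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    return np.convolve(padded, kernel, mode="valid")[: len(x)]


def gdd_spring_onset(
    curve: GddCurve,
    search_window: tuple[int, int] = (32, 212),
    smooth_days: int = 7,
) -> SpringOnsetRecord:
    """Day of the fastest acceleration of cumulative GDD ("GDD jerk").

    The cumulative curve is smoothed with a centered moving average (third
    differences amplify noise badly), then the third discrete difference is
    maximised inside the closed ``search_window``; ties break to the
    earliest day. A maximum at or below numerical tolerance (e.g. constant
    temperature, hence linear GDD) yields ``no_event``.
    """
    lo, hi = search_window
    days = curve.day_of_year
    if lo < days.min() or hi > days.max():
        raise ValueError("search window outside curve span")
    g = _moving_average(curve.cumulative_gdd, smooth_days)
    jerk = np.diff(g, n=3)
    # diff of order 3 at index i spans days[i] .. days[i+3]; assign to the center-right day
    jerk_days = days[2:-1]
    mask = (jerk_days >= lo) & (jerk_days <= hi)
    if not mask.any():
        raise ValueError("search window too narrow for third differences")
    j_win = jerk[mask]
    d_win = jerk_days[mask]
    i_best = int(np.argmax(j_win))  # argmax returns the first maximum -> earliest day
    if j_win[i_best] <= _JERK_TOL:
        return SpringOnsetRecord(curve.site_id, curve.year, "gdd", None, 0, Qc.NO_EVENT)
    return SpringOnsetRecord(curve.site_id, curve.year, "gdd", float(d_win[i_best]), 0, Qc.OK)


def fit_index_curve(
    pixel: pd.DataFrame,
    window: tuple[int, int],
    min_obs: int = 10,
    lam: float | None = None,
    pixel_id: str = "",
    kind: str = "",
) -> SmoothedIndexCurve | None:
    """Penalized-spline smooth of one pixel's index observations.

    ``pixel`` needs columns ``day_of_year`` and ``value``. Observations on
    the same day are averaged. Returns None (insufficient data) when fewer
    than ``min_obs`` observations fall inside the closed window.
    """
    lo, hi = window
    obs = pixel[(pixel["day_of_year"] >= lo) & (pixel["day_of_year"] <= hi)]
    obs = obs.groupby("day_of_year", as_index=False)["value"].mean().sort_values("day_of_year")
    if len(obs) < min_obs:
        return None
    x = obs["day_of_year"].to_numpy(dtype=float)
    y = obs["value"].to_numpy(dtype=float)
    spline = make_smoothing_spline(x, y, lam=lam)
    grid = np.arange(max(lo, int(x.min())), min(hi, int(x.max())) + 1)
    return SmoothedIndexCurve(pixel_id=pixel_id, kind=kind, day_of_year=grid, values=spline(grid.astype(float)))


def pixel_snowmelt(curve: SmoothedIndexCurve, threshold: float = 0.42) -> tuple[float | None, Qc]:
    """First day the smoothed NDSI drops below the snow threshold.

    A pixel qualifies only if it was snow-covered first (some earlier
    prediction at or above the threshold). Pixels that never reach the
    threshold were never snow-covered and are excluded; pixels that never
    drop below it have no melt event.
    """
    if curve.kind != "NDSI":
        raise ValueError(f"pixel_snowmelt requires an NDSI curve, got {curve.kind!r}")
    v = curve.values
    if not np.any(v >= threshold):
        return None, Qc.EXCLUDED
    below = v < threshold
    first_cover = int(np.argmax(v >= threshold))
    after = below.copy()
    after[: first_cover + 1] = False
    if not after.any():
        return None, Qc.NO_EVENT
    return float(curve.day_of_year[int(np.argmax(after))]), Qc.OK


def pixel_greenup(curve: SmoothedIndexCurve) -> tuple[float | None, Qc]:
    """Day of the largest day-to-day NDVI increase; ties break earliest."""
    if curve.kind != "NDVI":
        raise ValueError(f"pixel_greenup requires an NDVI curve, got {curve.kind!r}")
    inc = np.diff(curve.values)
    best = inc.max()
    if best <= 0:
        return None, Qc.NO_EVENT
    # earliest day within float tolerance of the maximum (exact ties included)
    i = int(np.argmax(inc >= best - 1e-12 * max(1.0, abs(best))))
    return float(curve.day_of_year[i]), Qc.OK


def site_snowmelt(pixel_days, site_id: str = "", year: int = 0) -> SpringOnsetRecord:
    """Median melt day across valid pixels (even count: mean of central pair)."""
    days = np.asarray([d for d in pixel_days if d is not None], dtype=float)
    if len(days) == 0:
        return SpringOnsetRecord(site_id, year, "snowmelt", None, 0, Qc.INSUFFICIENT_DATA)
    return SpringOnsetRecord(site_id, year, "snowmelt", float(np.median(days)), len(days), Qc.OK)


def site_greenup(pixel_days, site_id: str = "", year: int = 0) -> SpringOnsetRecord:
    """Mean green-up day across valid pixels (mean, not median, by protocol)."""
    days = np.asarray([d for d in pixel_days if d is not None], dtype=float)
    if len(days) == 0:
        return SpringOnsetRecord(site_id, year, "greenup", None, 0, Qc.INSUFFICIENT_DATA)
    return SpringOnsetRecord(site_id, year, "greenup", float(np.mean(days)), len(days), Qc.OK)


def area_onset(subarea_records: list[SpringOnsetRecord], method: str, area_id: str = "") -> SpringOnsetRecord:
    """Average subarea onset days to breeding-area level.

    QC degrades to insufficient_data when fewer than half the subareas have
    a valid day.
    """
    if any(r.method != method for r in subarea_records):
        raise ValueError("mixed methods in area aggregation")
    years = {r.year for r in subarea_records}
    if len(years) != 1:
        raise ValueError("mixed years in area aggregation")
    year = years.pop()
    valid = [r.day_of_year for r in subarea_records if r.qc_flag == Qc.OK and r.day_of_year is not None]
    n_px = sum(r.n_pixels_used for r in subarea_records)
    if len(valid) < max(1, len(subarea_records) / 2):
        return SpringOnsetRecord(area_id, year, method, None, n_px, Qc.INSUFFICIENT_DATA)
    return SpringOnsetRecord(area_id, year, method, float(np.mean(valid)), n_px, Qc.OK)


def site_index_onset(
    pixels: pd.DataFrame,
    kind: str,
    window: tuple[int, int],
    site_id: str = "",
    year: int = 0,
    cfg: AnalysisConfig | None = None,
) -> SpringOnsetRecord:
    """Full per-site pipeline: smooth every pixel, extract its event day, aggregate.

    ``pixels`` is a long table (pixel_id, day_of_year, value) of one site,
    year and index kind.
    """
    cfg = cfg or AnalysisConfig()
    days = []
    for pid, grp in pixels.groupby("pixel_id"):
        curve = fit_index_curve(grp, window, min_obs=cfg.min_pixel_obs, lam=cfg.spline_lam,
                                pixel_id=str(pid), kind=kind)
        if curve is None:
            continue
        day, qc = pixel_snowmelt(curve, cfg.ndsi_threshold) if kind == "NDSI" else pixel_greenup(curve)
        if qc == Qc.OK:
            days.append(day)
    if kind == "NDSI":
        return site_snowmelt(days, site_id=site_id, year=year)
    return site_greenup(days, site_id=site_id, year=year)
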