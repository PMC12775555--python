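"""Percentile migration-timing measures from resightings and counts.

From neckband resightings, each bird contributes its first and last
observation day at a site; the site's arrival percentile Arr_q is the first
day by which *over* q% of the season's birds have been seen (strict ">",
"over q%"), and the departure percentile Dep_q is the last day on which at
least q% are still present (">=", "still present").

From field counts (surveys every 1-3 days), counts are linearly
interpolated to daily resolution and the measures are taken relative to the
seasonal maximum: Peak is the day of the maximum (ties earliest), Arr_q the
first day the count reaches q% of the maximum and Dep_q the last such day.
The count-based definition has no published analogue and is flagged in the
output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ARRIVAL_LEVELS = (5, 50, 95)
DEPARTURE_LEVELS = (95, 50, 5)


@dataclass
class TimingMeasure:
    site_id: str
    year: int
    measure: str          # Arr5|Arr50|Arr95|Dep95|Dep50|Dep5|Peak
    day_of_year: float
    n: int                # individuals (resightings) or peak count (counts)
    source: str = "resightings"


def individual_window(resightings: pd.DataFrame, ring_id: str,
                      season: tuple[int, int] | None = None) -> tuple[int, int]:
    """(first, last) observation day of one bird within the season window."""
    sub = resightings[resightings["ring_id"] == ring_id]
    days = _season_days(sub, season)
    if len(days) == 0:
        raise ValueError(f"no resightings of {ring_id!r} in season")
    return int(days.min()), int(days.max())


def _season_days(df: pd.DataFrame, season: tuple[int, int] | None) -> np.ndarray:
    if "day_of_year" in df:
        days = df["day_of_year"].to_numpy(dtype=int)
    else:
        days = pd.to_datetime(df["date"]).dt.dayofyear.to_numpy()
    if season is not None:
        days = days[(days >= season[0]) & (days <= season[1])]
    return days


def arrival_percentile(first_days, q: int) -> int:
    """Smallest day d with #{first_day <= d} strictly exceeding q% of birds."""
    first = np.sort(np.asarray(list(first_days), dtype=int))
    n = len(first)
    if n == 0:
        raise ValueError("no individuals")
    need = q / 100.0 * n
    cum = np.arange(1, n + 1)
    idx = np.argmax(cum > need)
    if cum[idx] <= need:
        raise ValueError(f"arrival percentile q={q} never exceeded")
    return int(first[idx])


def departure_percentile(last_days, q: int) -> int:
    """Largest day d with #{last_day >= d} at least q% of birds."""
    last = np.sort(np.asarray(list(last_days), dtype=int))
    n = len(last)
    if n == 0:
        raise ValueError("no individuals")
    need = q / 100.0 * n
    # present(d) = n - #{last < d}; scan candidate days = observed last days
    candidates = np.unique(last)[::-1]
    for d in candidates:
        present = int((last >= d).sum())
        if present >= need:
            return int(d)
    raise ValueError(f"departure percentile q={q} never met")


def resighting_timing(resightings: pd.DataFrame, site_id: str, year: int,
                      season: tuple[int, int] | None = None,
                      levels=(5, 50, 95)) -> list[TimingMeasure]:
    """All arrival/departure percentile measures for one site-year."""
    sub = resightings.copy()
    if "day_of_year" not in sub:
        sub["day_of_year"] = pd.to_datetime(sub["date"]).dt.dayofyear
    if season is not None:
        sub = sub[(sub["day_of_year"] >= season[0]) & (sub["day_of_year"] <= season[1])]
    sub = sub[sub["site_id"] == site_id]
    if len(sub) == 0:
        return []
    per_bird = sub.groupby("ring_id")["day_of_year"].agg(["min", "max"])
    out = []
    for q in levels:
        out.append(TimingMeasure(site_id, year, f"Arr{q}",
                                 float(arrival_percentile(per_bird["min"], q)), len(per_bird)))
    for q in sorted(levels, reverse=True):
        out.append(TimingMeasure(site_id, year, f"Dep{q}",
                                 float(departure_percentile(per_bird["max"], q)), len(per_bird)))
    return out


def count_timing(counts: pd.DataFrame, site_id: str, year: int,
                 season: tuple[int, int] | None = None,
                 levels=(5, 50, 95)) -> list[TimingMeasure]:
    """Peak and percentile-of-maximum measures from interpolated daily counts.

    Requires at least 3 survey dates and a positive seasonal maximum.
    A coverage QC consideration: sparse surveys make the tails unreliable;
    the measures carry source="counts" so downstream users can filter.
    """
    sub = counts[counts["site_id"] == site_id].copy()
    if "day_of_year" not in sub:
        sub["day_of_year"] = pd.to_datetime(sub["date"]).dt.dayofyear
    if season is not None:
        sub = sub[(sub["day_of_year"] >= season[0]) & (sub["day_of_year"] <= season[1])]
    sub = sub.sort_values("day_of_year")
    if len(sub) < 3:
        raise ValueError("need at least 3 counting dates")
    days = sub["day_of_year"].to_numpy(dtype=float)
    vals = sub["count"].to_numpy(dtype=float)
    if vals.max() <= 0:
        raise ValueError("all counts zero")
    grid = np.arange(int(days.min()), int(days.max()) + 1)
    daily = np.interp(grid, days, vals)
    peak_val = daily.max()
    peak_day = int(grid[np.argmax(daily)])  # first maximum -> earliest tie
    out = [TimingMeasure(site_id, year, "Peak", float(peak_day), int(peak_val), source="counts")]
    for q in levels:
        thr = q / 100.0 * peak_val
        reach = daily >= thr
        out.append(TimingMeasure(site_id, year, f"Arr{q}",
                                 float(grid[np.argmax(reach)]), int(peak_val), source="counts"))
    for q in sorted(levels, reverse=True):
        thr = q / 100.0 * peak_val
        reach = daily >= thr
        last_idx = len(reach) - 1 - int(np.argmax(reach[::-1]))
        out.append(TimingMeasure(site_id, year, f"Dep{q}",
                                 float(grid[last_idx]), int(peak_val), source="counts"))
    return out


def validate_measures(measures: list[TimingMeasure]) -> None:
    """Check the ordering invariants Arr5 <= Arr50 <= Arr95, Dep95 <= Dep50 <= Dep5."""
    by = {m.measure: m.day_of_year for m in measures}
    if {"Arr5", "Arr50", "Arr95"} <= by.keys():
        if not by["Arr5"] <= by["Arr50"] <= by["Arr95"]:
            raise AssertionError("arrival percentiles out of order")
    if {"Dep95", "Dep50", "Dep5"} <= by.keys():
        if not by["Dep95"] <= by["Dep50"] <= by["Dep5"]:
            raise AssertionError("departure percentiles out of order")
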