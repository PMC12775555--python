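"""Analysis configuration: the pipeline's thresholds and windows.

The defaults collect the constants of the field protocol this pipeline
implements: the 15 km/h flight-speed cut, the >75% nest-attendance rule with
a minimum of 3 consecutive days and a 28-35 day successful-incubation run,
the NDSI 0.42 snow threshold, the stopover radius band, the latitude /
longitude boundaries of the two Arctic breeding areas, and the seasonal
windows for temperature and satellite-index extraction. Everything is
overridable from a YAML file; a config round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # track classification
    flight_speed_kmh: float = 15.0          # ground speed at/above which a fix is "flying"
    stopover_radius_km: float = 75.0        # within the documented 50-100 km band
    min_daily_fixes: int = 8                # data-quality floor (nominal rate is 16/day)
    stationarity_radius_m: float = 100.0    # "sitting still" displacement from the day median
    mostly_still_fraction: float = 0.5      # day counts as "mostly sitting still" above this
    attendance_radius_m: float = 50.0       # fix counts as on-nest within this of the candidate
    attendance_fraction: float = 0.75       # daily attendance must exceed this
    min_attendance_days: int = 3            # minimum consecutive-day run to accept a nest
    success_run_min_days: int = 28          # successful incubation run length bounds
    success_run_max_days: int = 35
    attendance_gap_tolerance: int = 0       # days <= 75% tolerated inside a run

    # breeding-area arrival boundaries (strict inequalities)
    svalbard_lat_boundary: float = 76.5640
    novaya_zemlya_lon_boundary: float = 51.4432

    # spring onset
    gdd_base_temp_c: float = 0.0
    gdd_window: tuple[int, int] = (1, 273)           # temperature series span, 1 Jan-30 Sep
    gdd_search_window: tuple[int, int] = (32, 212)   # onset searched 1 Feb-31 Jul
    gdd_smooth_days: int = 7                         # centered moving average before differencing
    ndsi_threshold: float = 0.42
    stopover_index_window: tuple[int, int] = (1, 181)    # 1 Jan-30 Jun
    breeding_index_window: tuple[int, int] = (74, 258)   # 15 Mar-15 Sep (non-leap doy)
    min_pixel_obs: int = 10
    spline_lam: float | None = None          # None -> GCV; fixed value for bit-reproducibility
    max_missing_day_fraction: float = 0.2

    # migration timing
    percentile_levels: tuple[int, ...] = (5, 50, 95)

    # statistics
    period_split_year: int = 2000            # first year of the late period
    alpha: float = 0.05

    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        # YAML has no tuple: store as lists, restore on load
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in raw.items():
            if k not in fields:
                raise ValueError(f"unknown config key: {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.attendance_fraction < 1:
            raise ValueError("attendance_fraction must be in (0, 1)")
        if not 50.0 <= self.stopover_radius_km <= 100.0:
            raise ValueError("stopover_radius_km outside the documented 50-100 km band")
        if self.flight_speed_kmh <= 0:
            raise ValueError("flight_speed_kmh must be positive")
        if not -1 < self.ndsi_threshold < 1:
            raise ValueError("ndsi_threshold must be a valid index value")
        if self.success_run_min_days > self.success_run_max_days:
            raise ValueError("success run bounds inverted")
        if self.min_attendance_days < 1:
            raise ValueError("min_attendance_days must be >= 1")
        for name in ("gdd_window", "gdd_search_window", "stopover_index_window", "breeding_index_window"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi <= 366):
                raise ValueError(f"{name} is not a valid closed day-of-year interval")
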