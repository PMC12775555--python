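"""Stage orchestration: synthesize -> onset -> tracks -> timing -> stats -> biometrics.

Each stage reads and writes plain CSV in a single run directory, so any
stage can be rerun in isolation. A RunReport (JSON) records the config
snapshot, seed, input digests, per-stage record counts and output paths;
identical config + seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biometrics as bio
from . import io as pio
from . import onset as on
from . import stats as st
from . import timing as tm
from . import tracks as tr
from .config import AnalysisConfig
from .synthetic import default_scenario, write_scenario

log = logging.getLogger("pinkfoot")

STAGE_ORDER = ["synth", "onset", "tracks", "timing", "stats", "biometrics"]
STAGE_INPUTS = {
    "onset": ["temperature.csv", "pixel_index.csv", "sites.csv"],
    "tracks": ["tracks.csv", "sites.csv"],
    "timing": ["resightings.csv", "counts.csv"],
    "stats": ["spring_onset.csv", "breeding_summary.csv"],
    "biometrics": ["captures.csv"],
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunReport:
    seed: int
    stages: list[str]
    config: dict
    input_digests: dict = field(default_factory=dict)
    record_counts: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    ok: bool = True
    error: str | None = None

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require_inputs(stage: str, run_dir: Path) -> None:
    for f in STAGE_INPUTS.get(stage, []):
        if not (run_dir / f).exists():
            raise PipelineError(
                f"stage {stage!r} requires {f!r}; run the producing stage first "
                f"(stage order: {' -> '.join(STAGE_ORDER)})")


def stage_synth(run_dir: Path, cfg: AnalysisConfig, n_individuals: int = 12,
                years=None, n_pixels: int = 15) -> dict:
    scen = default_scenario(cfg.seed, years=years, n_individuals=n_individuals,
                            index_missingness=0.1)
    write_scenario(scen, run_dir, n_pixels=n_pixels)
    return {"individuals": n_individuals, "site_years": len(scen.onsets)}


def stage_onset(run_dir: Path, cfg: AnalysisConfig) -> dict:
    _require_inputs("onset", run_dir)
    temps = pio.read_table(run_dir / "temperature.csv", "temperature")
    pixels = pio.read_table(run_dir / "pixel_index.csv", "pixel_index")
    sites = pio.read_table(run_dir / "sites.csv", "sites").set_index("site_id")
    temps["timestamp"] = pd.to_datetime(temps["timestamp"])
    temps["year"] = temps["timestamp"].dt.year
    pixels["date"] = pd.to_datetime(pixels["date"])
    pixels["year"] = pixels["date"].dt.year
    pixels["day_of_year"] = pixels["date"].dt.dayofyear
    records = []
    for (site_id, year), grp in temps.groupby(["site_id", "year"]):
        daily = on.daily_mean_temperature(grp)
        curve = on.cumulative_gdd(daily, cfg.gdd_base_temp_c, site_id=site_id, year=int(year),
                                  max_missing_fraction=cfg.max_missing_day_fraction)
        records.append(on.gdd_spring_onset(curve, cfg.gdd_search_window, cfg.gdd_smooth_days))
    for (site_id, year, kind), grp in pixels.groupby(["site_id", "year", "kind"]):
        role = sites.loc[site_id, "role"]
        window = cfg.breeding_index_window if role == "breeding" else cfg.stopover_index_window
        records.append(on.site_index_onset(grp, kind, window, site_id=site_id, year=int(year), cfg=cfg))
    df = pd.DataFrame([{
        "site_id": r.site_id, "year": r.year, "method": r.method,
        "day_of_year": r.day_of_year, "n_pixels_used": r.n_pixels_used,
        "qc_flag": r.qc_flag.value,
    } for r in records]).sort_values(["site_id", "year", "method"])
    df.to_csv(run_dir / "spring_onset.csv", index=False)
    return {"onset_records": len(df),
            "qc_not_ok": int((df["qc_flag"] != "ok").sum())}


def stage_tracks(run_dir: Path, cfg: AnalysisConfig) -> dict:
    _require_inputs("tracks", run_dir)
    fixes = pio.read_table(run_dir / "tracks.csv", "tracks")
    sites = pio.read_table(run_dir / "sites.csv", "sites")
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    fixes["year"] = fixes["timestamp"].dt.year
    stopovers = [tr.StopoverSite(r.site_id, r.lat, r.lon, cfg.stopover_radius_km)
                 for r in sites.itertuples() if r.role == "stopover"]
    breeding = {r.site_id: r for r in sites.itertuples() if r.role == "breeding"}
    visits, nests, summaries = [], [], []
    for (aid, year), track in fixes.groupby(["animal_id", "year"]):
        for site in stopovers:
            v = tr.visit_dates(track, site, cfg)
            if v is not None:
                visits.append(v)
        area_row = None
        for b in breeding.values():
            day = tr.breeding_arrival(track, b.boundary, cfg)
            if day is not None:
                area_row = (b, day)
                break
        nest = tr.detect_nest(track, cfg)
        if nest is not None:
            nests.append(nest)
        if area_row is not None:
            b, arr = area_row
            summaries.append(tr.BreedingSummary(
                animal_id=str(aid), year=int(year),
                breeding_area=b.route or b.site_id, arrival_day=arr,
                attempted=nest is not None,
                laying_day=nest.laying_day if nest else None,
                success=nest.success if nest else None,
                pre_laying_interval_days=(nest.laying_day - arr) if nest else None,
            ))
    pd.DataFrame([dataclasses.asdict(v) for v in visits]).to_csv(run_dir / "visits.csv", index=False)
    nest_rows = [{k: v for k, v in dataclasses.asdict(n).items() if k != "attendance"} for n in nests]
    pd.DataFrame(nest_rows).to_csv(run_dir / "nests.csv", index=False)
    pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(run_dir / "breeding_summary.csv", index=False)
    return {"visits": len(visits), "nests": len(nests), "summaries": len(summaries)}


def stage_timing(run_dir: Path, cfg: AnalysisConfig) -> dict:
    _require_inputs("timing", run_dir)
    resights = pio.read_table(run_dir / "resightings.csv", "resightings")
    counts = pio.read_table(run_dir / "counts.csv", "counts")
    for df in (resights, counts):
        df["date"] = pd.to_datetime(df["date"])
        df["year"] = df["date"].dt.year
        df["day_of_year"] = df["date"].dt.dayofyear
    measures = []
    for (site_id, year), grp in resights.groupby(["site_id", "year"]):
        measures += tm.resighting_timing(grp, site_id, int(year), levels=cfg.percentile_levels)
    for (site_id, year), grp in counts.groupby(["site_id", "year"]):
        measures += tm.count_timing(grp, site_id, int(year), levels=cfg.percentile_levels)
    df = pd.DataFrame([dataclasses.asdict(m) for m in measures])
    df.to_csv(run_dir / "timing_measures.csv", index=False)
    return {"timing_measures": len(df)}


def stage_stats(run_dir: Path, cfg: AnalysisConfig) -> dict:
    _require_inputs("stats", run_dir)
    onset_df = pd.read_csv(run_dir / "spring_onset.csv")
    summ = pd.read_csv(run_dir / "breeding_summary.csv")
    ok = onset_df[onset_df["qc_flag"] == "ok"]
    series = {(s, m): grp.set_index("year")["day_of_year"]
              for (s, m), grp in ok.groupby(["site_id", "method"])}
    trends = []
    for (site_id, method), s in sorted(series.items()):
        if len(s) >= 3:
            t = st.linear_trend(s, site_id=site_id, variable=method)
            trends.append(dataclasses.asdict(t))
    pd.DataFrame(trends).to_csv(run_dir / "trends.csv", index=False)

    pred_rows, comp_rows = [], []
    pairs = [("trondelag", "svalbard"), ("oulu", "novaya_zemlya")]
    for a, b in pairs:
        for method in ("gdd", "snowmelt", "greenup"):
            sa, sb = series.get((a, method)), series.get((b, method))
            if sa is None or sb is None or len(sa) < 3 or len(sb) < 3:
                continue
            try:
                pr = st.cross_site_predictability(st.detrend(sa), st.detrend(sb), pair=(a, b))
            except ValueError:
                continue
            pred_rows.append({"site_a": a, "site_b": b, "method": method,
                              "slope": pr.slope, "se": pr.se, "p": pr.p, "n": pr.n})
    pd.DataFrame(pred_rows).to_csv(run_dir / "predictability.csv", index=False)

    for method in ("gdd", "snowmelt", "greenup"):
        sa, sb = series.get(("svalbard", method)), series.get(("novaya_zemlya", method))
        if sa is None or sb is None:
            continue
        shared = sa.index.intersection(sb.index)
        if len(shared) >= 2:
            c = st.within_year_difference(sa, sb, term=f"novaya_zemlya-svalbard:{method}")
            comp_rows.append(dataclasses.asdict(c))
        if len(shared) >= 3 and sa[shared].std() > 0 and sb[shared].std() > 0:
            r, p = st.correlate(sa, sb)
            comp_rows.append({"term": f"cor(svalbard,novaya_zemlya):{method}",
                              "estimate": r, "se": np.nan, "stat": np.nan, "p": p, "df": np.nan})

    report = {"models": []}
    if len(summ):
        summ = summ.rename(columns={"breeding_area": "area"})
        onset_b = ok[(ok["method"] == "gdd") & ok["site_id"].isin(["svalbard", "novaya_zemlya"])]
        route_of = {"svalbard": "traditional", "novaya_zemlya": "new"}
        onset_b = onset_b.assign(area=onset_b["site_id"].map(route_of))
        summ = summ.merge(onset_b[["area", "year", "day_of_year"]].rename(
            columns={"day_of_year": "onset_day"}), on=["area", "year"], how="left")
        summ["attempted"] = summ["attempted"].astype(int)
        if summ["area"].nunique() == 2 and summ["onset_day"].notna().all() and summ["onset_day"].std() > 0:
            fit = st.propensity_model(summ)
            for c in fit.comparisons:
                comp_rows.append({"term": f"propensity:{c.term}", "estimate": c.estimate,
                                  "se": c.se, "stat": c.stat, "p": c.p, "df": np.nan})
            report["models"].append({
                "name": "propensity", "formula": fit.spec.fixed, "n": fit.n_obs,
                "converged": fit.converged, "random_sd": fit.random_sd,
                "estimates": {c.term: c.estimate for c in fit.comparisons},
            })
    pd.DataFrame(comp_rows).to_csv(run_dir / "comparisons.csv", index=False)
    with open(run_dir / "model_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return {"trends": len(trends), "predictability": len(pred_rows), "comparisons": len(comp_rows)}


def stage_biometrics(run_dir: Path, cfg: AnalysisConfig) -> dict:
    _require_inputs("biometrics", run_dir)
    captures = pio.read_table(run_dir / "captures.csv", "captures")
    captures["date"] = pd.to_datetime(captures["date"])
    captures["year"] = captures["date"].dt.year
    captures["day_of_year"] = captures["date"].dt.dayofyear
    valid, rejected = bio.validate_captures(captures)
    if len(rejected):
        log.warning("rejected %d capture rows: %s", len(rejected),
                    rejected["reason"].unique().tolist())
    fits = {s: bio.fit_allometry(valid, s) for s in sorted(valid["sex"].unique())}
    pd.DataFrame([dataclasses.asdict(f) for f in fits.values()]).to_csv(
        run_dir / "allometry.csv", index=False)
    cond = bio.condition_table(valid, fits)
    cond[["animal_id", "sex", "route", "wing_mm", "mass_g", "expected_mass_g", "condition"]].to_csv(
        run_dir / "condition.csv", index=False)
    rows = []
    if valid["route"].nunique() == 2 and valid["sex"].nunique() == 2 and valid["year"].nunique() >= 1:
        for resp, fit in bio.compare_routes(valid).items():
            for c in fit.comparisons:
                rows.append({"response": resp, "term": c.term, "estimate": c.estimate,
                             "se": c.se, "stat": c.stat, "p": c.p, "df": c.df})
    pd.DataFrame(rows).to_csv(run_dir / "biometric_comparisons.csv", index=False)
    return {"captures": len(valid), "rejected": len(rejected), "allometry_fits": len(fits)}


STAGE_FUNCS = {
    "synth": stage_synth, "onset": stage_onset, "tracks": stage_tracks,
    "timing": stage_timing, "stats": stage_stats, "biometrics": stage_biometrics,
}


def run_pipeline(run_dir: str | Path, cfg: AnalysisConfig | None = None,
                 stages: list[str] | None = None, **synth_kwargs) -> RunReport:
    """Execute the selected stages in dependency order and write a RunReport."""
    cfg = cfg or AnalysisConfig()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in (stages or STAGE_ORDER)]
    if not stages:
        raise PipelineError("no valid stages selected")
    report = RunReport(seed=cfg.seed, stages=stages, config=dataclasses.asdict(cfg))
    try:
        for stage in stages:
            for f in STAGE_INPUTS.get(stage, []):
                p = run_dir / f
                if p.exists():
                    report.input_digests[f] = _digest(p)
            fn = STAGE_FUNCS[stage]
            counts = fn(run_dir, cfg, **(synth_kwargs if stage == "synth" else {}))
            report.record_counts[stage] = counts
            log.info("stage %s: %s", stage, counts)
    except Exception as exc:
        report.ok = False
        report.error = f"{type(exc).__name__}: {exc}"
        report.write(run_dir / "run_report.json")
        raise
    report.outputs = sorted(str(p.name) for p in run_dir.glob("*.csv"))
    report.write(run_dir / "run_report.json")
    return report
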