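"""CSV schemas and ingest validation.

All tabular IO is plain UTF-8 CSV with a header row and ISO-8601 dates.
Validation never mutates inputs: it returns row-level violation records
(file, row, column, reason) and the pipeline fails fast on any violation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

SCHEMAS = {
    "tracks": {"required": ["animal_id", "timestamp", "lat", "lon"],
               "optional": ["ground_speed"]},
    "temperature": {"required": ["site_id", "timestamp", "temp_c"], "optional": []},
    "pixel_index": {"required": ["pixel_id", "site_id", "kind", "date", "value"], "optional": []},
    "resightings": {"required": ["ring_id", "site_id", "date"], "optional": []},
    "counts": {"required": ["site_id", "date", "count"], "optional": []},
    "captures": {"required": ["animal_id", "date", "site", "route", "sex",
                              "head_mm", "wing_mm", "mass_g"], "optional": []},
    "sites": {"required": ["site_id", "lat", "lon", "role"], "optional": ["boundary", "route"]},
}


@dataclass
class Violation:
    file: str
    row: int | None
    column: str | None
    reason: str


def _check_parse_dates(df: pd.DataFrame, col: str, name: str, violations: list[Violation]) -> None:
    parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
    for idx in df.index[parsed.isna() & df[col].notna()]:
        violations.append(Violation(name, int(idx), col, f"non-ISO timestamp: {df.loc[idx, col]!r}"))


def validate_table(df: pd.DataFrame, schema: str, name: str | None = None) -> list[Violation]:
    name = name or schema
    spec = SCHEMAS[schema]
    v: list[Violation] = []
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        v.append(Violation(name, None, ",".join(missing), "missing required column(s)"))
        return v
    if schema in ("tracks", "sites"):
        bad_lat = df.index[(df["lat"].abs() > 90) | df["lat"].isna()]
        bad_lon = df.index[(df["lon"].abs() > 180) | df["lon"].isna()]
        v += [Violation(name, int(i), "lat", f"latitude out of range: {df.loc[i, 'lat']}") for i in bad_lat]
        v += [Violation(name, int(i), "lon", f"longitude out of range: {df.loc[i, 'lon']}") for i in bad_lon]
    if schema in ("tracks", "temperature"):
        _check_parse_dates(df, "timestamp", name, v)
    if schema in ("pixel_index", "resightings", "counts", "captures"):
        _check_parse_dates(df, "date", name, v)
    if schema == "pixel_index":
        bad = df.index[(df["value"].abs() > 1) | df["value"].isna()]
        v += [Violation(name, int(i), "value", f"index value outside [-1, 1]: {df.loc[i, 'value']}") for i in bad]
    if schema == "counts":
        bad = df.index[(df["count"] < 0) | df["count"].isna()]
        v += [Violation(name, int(i), "count", "negative or missing count") for i in bad]
    return v


def validate_inputs(paths: dict[str, str | Path]) -> list[Violation]:
    """Validate each named input file against its schema; never mutates files."""
    out: list[Violation] = []
    for schema, path in paths.items():
        path = Path(path)
        if not path.exists():
            out.append(Violation(str(path), None, None, "file not found"))
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # unreadable / malformed file
            out.append(Violation(str(path), None, None, f"unreadable: {exc}"))
            continue
        out.extend(validate_table(df, schema, name=str(path)))
    return out


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    violations = validate_table(df, schema, name=str(path))
    if violations:
        lines = "; ".join(f"{v.file} row {v.row} [{v.column}]: {v.reason}" for v in violations[:10])
        raise ValueError(f"{len(violations)} schema violation(s) in {path}: {lines}")
    return df
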