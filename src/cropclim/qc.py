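"""Yield construction and data-quality filters for production/area tables.

Yield is production divided by harvested area (t/ha).  National statistics
are self-reported and of uneven quality; two automatic rules plus a
config-driven manual list handle the known failure modes:

* records with non-positive area or non-positive derived yield are rejected;
* if a series reports *exactly* the same production in two or more
  consecutive years (a tell-tale of carried-forward numbers), only the years
  strictly before the first such run or strictly after the last one are kept
  -- whichever segment is longer;
* individually implausible observations are removed via an explicit
  exclusion list (they cannot be detected by a rule).

Every action is recorded in a QC log (a list of dict entries, serializable
as JSON lines).  Filters only ever drop rows; retained values are never
altered.
"""

from __future__ import annotations

import json
import warnings

import pandas as pd

__all__ = [
    "compute_yield",
    "filter_repeated_production",
    "apply_exclusions",
    "write_qc_log",
]


def compute_yield(records: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Per-year yield (t/ha) from production (t) and area (ha).

    Returns the yield table (region, crop, year, yield, production, area)
    sorted by year within series, plus a QC log of rejected records.
    """
    req = {"region", "crop", "year", "production", "area"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns: {sorted(missing)}")
    dup = records.duplicated(["region", "crop", "year"])
    if dup.any():
        raise ValueError("duplicate (region, crop, year) records")

    log: list[dict] = []
    df = records.copy()
    bad_area = df["area"] <= 0
    for _, row in df[bad_area].iterrows():
        log.append({"filter": "positivity", "region": row["region"],
                    "crop": row["crop"], "year": int(row["year"]),
                    "reason": f"non-positive area {row['area']}"})
    df = df[~bad_area].copy()
    df["yield"] = df["production"] / df["area"]
    bad_yield = df["yield"] <= 0
    for _, row in df[bad_yield].iterrows():
        log.append({"filter": "positivity", "region": row["region"],
                    "crop": row["crop"], "year": int(row["year"]),
                    "reason": f"non-positive yield {row['yield']}"})
    df = df[~bad_yield]
    cols = ["region", "crop", "year", "yield", "production", "area"]
    return df[cols].sort_values(["region", "crop", "year"]).reset_index(drop=True), log


def _runs_of_repeats(values) -> list[tuple[int, int]]:
    """(start, end) index pairs of runs of >= 2 identical consecutive values."""
    runs, start = [], 0
    for i in range(1, len(values)):
        if values[i] != values[i - 1]:
            if i - start >= 2:
                runs.append((start, i - 1))
            start = i
    if len(values) - start >= 2:
        runs.append((start, len(values) - 1))
    return runs


def filter_repeated_production(
    series: pd.DataFrame, min_years: int = 20
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop the shorter side of any consecutive-identical-production runs.

    For a single (region, crop) series sorted by year: if any production
    value repeats in consecutive years, keep the longer of (a) the years
    strictly after the end of the last run, or (b) the years strictly before
    the start of the first run.  Ties go to the more recent segment.  A
    kept segment shorter than ``min_years`` is flagged unusable (the series
    comes back empty, with a log entry saying so).
    """
    if len(series) < 2:
        return series, []
    if series["region"].nunique() > 1 or series["crop"].nunique() > 1:
        raise ValueError("filter_repeated_production expects a single series")
    s = series.sort_values("year").reset_index(drop=True)
    runs = _runs_of_repeats(s["production"].to_list())
    if not runs:
        return s, []
    first_start = runs[0][0]
    last_end = runs[-1][1]
    after = s.iloc[last_end + 1:]
    before = s.iloc[:first_start]
    kept = after if len(after) >= len(before) else before
    side = "after" if len(after) >= len(before) else "before"
    entry = {
        "filter": "repeated_production",
        "region": s.loc[0, "region"], "crop": s.loc[0, "crop"],
        "kept_side": side,
        "kept_years": [int(kept["year"].min()), int(kept["year"].max())] if len(kept) else [],
        "dropped_n": int(len(s) - len(kept)),
    }
    if len(kept) < min_years:
        entry["unusable"] = True
        entry["reason"] = (f"kept segment has {len(kept)} years, "
                           f"below minimum {min_years}")
        return kept.iloc[0:0], [entry]
    return kept.reset_index(drop=True), [entry]


def apply_exclusions(
    table: pd.DataFrame, exclusions: list[dict]
) -> tuple[pd.DataFrame, list[dict]]:
    """Remove explicitly listed (region, crop, year / year-range) rows.

    Each exclusion entry has keys region, crop and either ``year`` or
    ``years`` = [first, last] inclusive.  Entries that match nothing raise a
    warning, not an error.
    """
    df = table.copy()
    log: list[dict] = []
    for exc in exclusions:
        if "year" in exc:
            lo = hi = int(exc["year"])
        else:
            lo, hi = map(int, exc["years"])
        sel = ((df["region"] == exc["region"]) & (df["crop"] == exc["crop"])
               & df["year"].between(lo, hi))
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"exclusion matched no rows: {exc}", stacklevel=2)
        else:
            df = df[~sel]
        log.append({"filter": "manual_exclusion", "region": exc["region"],
                    "crop": exc["crop"], "years": [lo, hi], "removed": n})
    return df.reset_index(drop=True), log


def write_qc_log(log: list[dict], path) -> None:
    with open(path, "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
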