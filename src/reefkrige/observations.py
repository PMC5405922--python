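"""Reading, validating and quality-filtering severity-coded bleaching reports.

Report tables follow the ReefBase-style schema: one row per independent
bleaching observation with country/site metadata, decimal-degree
coordinates, date fields, percent bleached and an ordinal severity code

    -1 unknown extent, 0 none, 1 mild (1-10%), 2 moderate (11-50%),
    3 severe (>50%)

plus mortality, survey type and provenance columns.  ``database_code`` is
1 for records originating from ReefBase and 2 for newly collected records.

Malformed rows are never silently dropped: every reader/filter returns the
rejected rows with machine-readable reasons so record counts always
partition (kept + removed = read).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical column order of the report schema.
REPORT_COLUMNS = [
    "country", "location", "site_name", "latitude", "longitude", "date",
    "month", "year", "depth", "severity_code", "percent_bleached",
    "mortality_code", "percent_mortality", "survey_type", "source", "name",
    "citation", "comments", "entry_code", "database_code",
]

#: Columns a table must provide (plus one of percent_bleached / severity_code).
MANDATORY_COLUMNS = ["latitude", "longitude", "year"]

#: Default substrings marking a reported cause as non-thermal (or a purely
#: local thermal event); matched case-insensitively against comments.
NON_THERMAL_KEYWORDS = ("freshwater", "runoff", "tidal", "exposure", "effluent", "cold")

_NUMERIC = {
    "latitude": float, "longitude": float, "depth": float,
    "percent_bleached": float, "percent_mortality": float,
    "month": "Int64", "year": "Int64", "severity_code": "Int64",
    "mortality_code": "Int64", "database_code": "Int64",
}


class SchemaError(ValueError):
    """A report table is missing mandatory columns."""


def assign_severity(percent_bleached) -> int:
    """Severity code from percent bleached.

    missing -> -1; 0 -> 0; (0, 10] -> 1; (10, 50] -> 2; (50, 100] -> 3.
    Band edges are closed on the right so the printed labels "1-10%",
    "11-50%", ">50%" are exclusive and exhaustive; fractional percents
    between bands (e.g. 10.5) fall in the higher band.
    """
    if percent_bleached is None or (isinstance(percent_bleached, float) and math.isnan(percent_bleached)):
        return -1
    p = float(percent_bleached)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percent bleached {p} outside [0, 100]")
    if p == 0.0:
        return 0
    if p <= 10.0:
        return 1
    if p <= 50.0:
        return 2
    return 3


def assign_severity_vector(percent: pd.Series) -> pd.Series:
    """Vectorised :func:`assign_severity` (no range checking)."""
    p = pd.to_numeric(percent, errors="coerce")
    out = pd.Series(-1, index=percent.index, dtype="Int64")
    out[p == 0.0] = 0
    out[(p > 0.0) & (p <= 10.0)] = 1
    out[(p > 10.0) & (p <= 50.0)] = 2
    out[p > 50.0] = 3
    return out


def _canonicalise_header(columns: Iterable[str]) -> dict:
    return {c: c.strip().lower() for c in columns}


def read_reports(path, sep: str = ",") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a report table; returns ``(reports, rejects)``.

    Headers are matched case-insensitively and order-free against the
    canonical schema.  Rows failing row-level validation (unparseable or
    out-of-range coordinates, missing year, percent outside [0, 100], a
    stored severity code contradicting the percent-bleached band) land in
    the rejects frame with columns ``row_index, reason, detail`` plus the
    original fields.  Missing optional fields are preserved as missing.

    Raises :class:`SchemaError` if latitude, longitude, year, or both of
    percent_bleached/severity_code are absent from the header.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw = raw.rename(columns=_canonicalise_header(raw.columns))
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column: {col}")
    if "percent_bleached" not in raw.columns and "severity_code" not in raw.columns:
        raise SchemaError("missing mandatory column: percent_bleached or severity_code")
    for col in REPORT_COLUMNS:
        if col not in raw.columns:
            raw[col] = ""
    raw = raw[REPORT_COLUMNS]

    df = raw.copy()
    for col, typ in _NUMERIC.items():
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if typ != float:
            df[col] = df[col].astype("Int64")

    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        new = mask & (reasons == "")
        reasons[new] = reason

    flag(df["latitude"].isna(), "latitude missing or unparseable")
    flag(df["longitude"].isna(), "longitude missing or unparseable")
    flag((df["latitude"] < -90) | (df["latitude"] > 90), "latitude out of range")
    flag((df["longitude"] < -180) | (df["longitude"] > 180), "longitude out of range")
    flag(df["year"].isna(), "year missing or unparseable")
    pb = df["percent_bleached"]
    flag(pb.notna() & ((pb < 0) | (pb > 100)), "percent_bleached out of range")
    pm = df["percent_mortality"]
    flag(pm.notna() & ((pm < 0) | (pm > 100)), "percent_mortality out of range")
    flag(df["severity_code"].notna() & ~df["severity_code"].isin([-1, 0, 1, 2, 3]), "severity_code invalid")
    derived = assign_severity_vector(df["percent_bleached"])
    both = df["severity_code"].notna() & df["percent_bleached"].notna()
    flag(both & (df["severity_code"] != derived), "severity_percent_mismatch")

    bad = reasons != ""
    rejects = raw.loc[bad].copy()
    rejects.insert(0, "row_index", rejects.index)
    rejects.insert(1, "reason", reasons[bad].to_numpy())
    kept = df.loc[~bad].copy()
    # derive severity where only percent was given
    need = kept["severity_code"].isna()
    kept.loc[need, "severity_code"] = assign_severity_vector(kept.loc[need, "percent_bleached"])
    missing_db = kept["database_code"].isna()
    kept.loc[missing_db, "database_code"] = 2
    return kept.reset_index(drop=True), rejects.reset_index(drop=True)


def write_reports(reports: pd.DataFrame, path) -> None:
    """Write a report table in the canonical schema (CSV, empty = missing)."""
    out = reports.copy()
    for col in REPORT_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    out[REPORT_COLUMNS].to_csv(path, index=False)


def qc_filter(
    reports: pd.DataFrame,
    reef_grid=None,
    keywords: Sequence[str] = NON_THERMAL_KEYWORDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quality-control filter; returns ``(kept, removed)`` with reasons.

    Removes (a) records whose comments match a non-thermal-cause keyword
    (freshwater runoff, tidal exposure, power-plant effluent, cold-water
    events, ...), and (b) records whose coordinates fall on a known land
    cell of the reef mask ("bleaching reported on land").  The two output
    frames partition the input; ``removed`` carries ``reason`` in
    ``{non_thermal, off_reef}`` and a free-text ``detail``.
    """
    comments = reports.get("comments", pd.Series("", index=reports.index)).astype(str).str.lower()
    reason = pd.Series("", index=reports.index, dtype=object)
    detail = pd.Series("", index=reports.index, dtype=object)
    for kw in keywords:
        hit = comments.str.contains(kw.lower(), regex=False) & (reason == "")
        reason[hit] = "non_thermal"
        detail[hit] = f"comment matched keyword {kw!r}"
    if reef_grid is not None and len(reef_grid.land_cells) and len(reports):
        cells = reef_grid.cell_index(reports["latitude"].to_numpy(float), reports["longitude"].to_numpy(float))
        on_land = np.isin(cells, np.fromiter(reef_grid.land_cells, dtype=np.int64)) & (reason == "").to_numpy()
        reason[on_land] = "off_reef"
        detail[on_land] = "coordinates fall on a land cell (bleaching reported on land)"
    removed = reports.loc[reason != ""].copy()
    removed["reason"] = reason[reason != ""]
    removed["detail"] = detail[reason != ""]
    kept = reports.loc[reason == ""].copy()
    return kept.reset_index(drop=True), removed.reset_index(drop=True)


def collapse_duplicates(reports: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse exact duplicate observations.

    An independent record is a unique (latitude, longitude, year,
    severity_code) tuple; exact duplicates are collapsed to the first
    occurrence and the number of dropped rows is returned for the log.
    """
    key = ["latitude", "longitude", "year", "severity_code"]
    before = len(reports)
    out = reports.drop_duplicates(subset=key, keep="first").reset_index(drop=True)
    return out, before - len(out)
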