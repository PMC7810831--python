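"""Reading SRDB-dialect CSV tables and applying the record filters.

The filters reproduce the selection used for the global trend analysis:
annual fluxes only, complete spatial/temporal metadata, natural
(non-agricultural, unmanipulated) ecosystems, IRGA or gas-chromatography
flux measurements, the 1987+ study period, and a single-pass +/-3 SD
outlier screen on the surviving population. Every step's removal count is
logged in a :class:`FilterReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyResultError, FormatError

__all__ = [
    "SRDB_COLUMN_MAP",
    "FilterReport",
    "read_srdb",
    "apply_filters",
    "split_periods",
    "year_of",
]

#: SRDB column -> normalized field name.
SRDB_COLUMN_MAP = {
    "Record_number": "record_id",
    "Study_number": "study_id",
    "Latitude": "latitude",
    "Longitude": "longitude",
    "Elevation": "elevation",
    "Manipulation": "manipulation",
    "Ecosystem_type": "ecosystem",
    "Leaf_habit": "leaf_habit",
    "Stage": "stage",
    "Biome": "biome",
    "Meas_method": "meas_method",
    "Partition_method": "partition_method",
    "Rs_annual": "rs_annual",
    "Rh_annual": "rh_annual",
    "Ra_annual": "ra_annual",
    "Study_midyear": "mid_year",
    "YearsOfObs": "duration_years",
}

_MANDATORY = [
    "Record_number", "Study_number", "Latitude", "Longitude",
    "Manipulation", "Ecosystem_type", "Meas_method",
    "Rs_annual", "Study_midyear", "YearsOfObs",
]

_NUMERIC = [
    "latitude", "longitude", "elevation", "rs_annual", "rh_annual",
    "ra_annual", "mid_year", "duration_years",
]

#: Accepted flux-measurement vocabulary (lower-case), incl. synonyms.
ACCEPTED_METHODS = {
    "irga",
    "infrared gas analyzer",
    "infrared gas analyzers",
    "gas chromatography",
    "gc",
}


@dataclass
class FilterReport:
    """Ordered per-criterion removal counts for one filtering run."""

    n_input: int
    steps: list[tuple[str, int]] = field(default_factory=list)
    n_output: int = 0

    def add(self, name: str, removed: int) -> None:
        self.steps.append((name, int(removed)))

    def check(self) -> bool:
        return self.n_input - sum(r for _, r in self.steps) == self.n_output

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "removed": [{"criterion": n, "removed": r} for n, r in self.steps],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def read_srdb(source) -> pd.DataFrame:
    """Read an SRDB-dialect CSV (path, buffer, or DataFrame) into normalized form.

    Unparseable numeric cells become NaN rather than errors; a missing
    mandatory column raises :class:`FormatError` naming the column.
    """
    if isinstance(source, pd.DataFrame):
        raw = source.copy()
    else:
        raw = pd.read_csv(source, encoding="utf-8", low_memory=False)
    missing = [c for c in _MANDATORY if c not in raw.columns]
    if missing:
        raise FormatError(f"missing mandatory SRDB column(s): {', '.join(missing)}")
    cols = {src: dst for src, dst in SRDB_COLUMN_MAP.items() if src in raw.columns}
    df = raw[list(cols)].rename(columns=cols)
    for col in _NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def year_of(records: pd.DataFrame) -> pd.Series:
    """Calendar year of each record: integer part of the decimal mid-year."""
    return np.floor(records["mid_year"]).astype("Int64")


def apply_filters(
    records: pd.DataFrame,
    period: tuple[int, int] = (1987, 2016),
    sd_limit: float = 3.0,
    flux: str = "rs",
    outlier_population: str = "filtered",
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the record-selection criteria in order and log removals.

    Steps: (1) annual flux present; (2) coordinates and mid-year present;
    (3) non-agricultural, manipulation "None"; (4) IRGA/GC measurement
    method; (5) mid-year's calendar year inside ``period``; (6) one-pass
    outlier screen at ``mean +/- sd_limit * SD``. By default the outlier
    statistics come from the already-filtered population
    (``outlier_population="filtered"``); ``"input"`` uses the pre-filter
    flux population instead, for sensitivity checks.
    """
    flux_col = f"{flux}_annual"
    if flux_col not in records.columns:
        raise FormatError(f"records lack a {flux_col} column")
    report = FilterReport(n_input=len(records))
    df = records

    keep = df[flux_col].notna()
    report.add("annual_flux_missing", (~keep).sum())
    df = df[keep]

    keep = (
        df["latitude"].notna() & df["longitude"].notna() & df["mid_year"].notna()
    )
    report.add("missing_space_time", (~keep).sum())
    df = df[keep]

    eco = df["ecosystem"].astype(str).str.lower()
    manip = df["manipulation"].astype(str).str.strip().str.lower()
    keep = ~eco.str.contains("agricult") & manip.isin({"none", "nan", ""})
    report.add("agricultural_or_manipulated", (~keep).sum())
    df = df[keep]

    meth = df["meas_method"].astype(str).str.strip().str.lower()
    keep = meth.isin(ACCEPTED_METHODS)
    report.add("method_not_irga_gc", (~keep).sum())
    df = df[keep]

    yr = np.floor(df["mid_year"])
    keep = (yr >= period[0]) & (yr <= period[1])
    report.add("outside_period", (~keep).sum())
    df = df[keep]

    if len(df):
        if outlier_population == "filtered":
            pop = df[flux_col]
        else:
            pop = records[flux_col].dropna()
        mu, sd = pop.mean(), pop.std(ddof=1)
        if sd > 0:
            keep = (df[flux_col] - mu).abs() <= sd_limit * sd
        else:
            keep = pd.Series(True, index=df.index)
        report.add(f"outlier_{sd_limit:g}sd", (~keep).sum())
        df = df[keep]
    else:
        report.add(f"outlier_{sd_limit:g}sd", 0)

    report.n_output = len(df)
    if report.n_output == 0:
        raise EmptyResultError("no records survive the filters")
    return df.copy(), report


def split_periods(
    records: pd.DataFrame, breakpoint: int = 1999
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into early (year <= breakpoint) and late (year > breakpoint).

    With the published breakpoint between 1999 and 2000, ``breakpoint=1999``
    yields the early period 1987-1999 and the late period 2000 onward.
    """
    yr = np.floor(records["mid_year"])
    early = records[yr <= breakpoint]
    late = records[yr > breakpoint]
    return early.copy(), late.copy()
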