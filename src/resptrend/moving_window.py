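"""One-dimensional moving subset window analyses.

Overlapping fixed-width subsets are advanced by a fixed step along the
measurement year (decadal windows), signed latitude, or SOC stock, and
the Rs-versus-year regression (OLS plus Theil–Sen) is computed inside
each window. Windows with too few records or no year spread are flagged,
never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateSeriesError
from .srdb_ingest import year_of
from .trend_models import trend

__all__ = ["WindowScheme", "build_windows", "window_trends", "axis_values"]

_AXES = {"year", "latitude", "soc"}

#: Default (width, step, upper_cap, origin) per axis: a decade advanced
#: annually; 30 degrees of latitude advanced by 1 degree (origin at the
#: data minimum); 60 Mg/ha of SOC advanced by 10 from 0 up to 380.
DEFAULTS = {
    "year": (10.0, 1.0, None, None),
    "latitude": (30.0, 1.0, None, None),
    "soc": (60.0, 10.0, 380.0, 0.0),
}


@dataclass
class WindowScheme:
    axis: str
    width: Optional[float] = None
    step: Optional[float] = None
    origin: Optional[float] = None
    upper_cap: Optional[float] = None
    min_n: int = 10

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ConfigurationError(f"unknown window axis {self.axis!r}")
        dw, ds, dcap, dorigin = DEFAULTS[self.axis]
        if self.width is None:
            self.width = dw
        if self.step is None:
            self.step = ds
        if self.upper_cap is None:
            self.upper_cap = dcap
        if self.origin is None:
            self.origin = dorigin
        if self.step <= 0:
            raise ConfigurationError("step must be positive")
        if self.width < self.step:
            raise ConfigurationError("width must be >= step")


def axis_values(records: pd.DataFrame, axis: str) -> np.ndarray:
    """Per-record window-axis value (year uses the calendar year)."""
    if axis == "year":
        return year_of(records).astype(float).values
    if axis == "latitude":
        return records["latitude"].values.astype(float)
    if axis == "soc":
        return records["soc"].values.astype(float)
    raise ConfigurationError(f"unknown window axis {axis!r}")


def build_windows(
    values: np.ndarray, scheme: WindowScheme
) -> list[tuple[float, float]]:
    """Inclusive [lower, upper] window bounds along the scheme axis.

    Year windows are decade spans counted inclusively (width 10 -> a
    window covers 10 calendar years, upper = lower + 9), starting at the
    earliest record year and advancing by the step until the last span
    ends at the latest year. Latitude/SOC windows are spans
    [L, L + width] from the origin (data minimum rounded down, or 0 for
    SOC) advanced by the step; the last window ends at the upper cap when
    set, else at the data maximum.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ConfigurationError("no finite values on the window axis")
    lo, hi = float(v.min()), float(v.max())

    if scheme.axis == "year":
        width = scheme.width - 1.0  # inclusive span of calendar years
        limit = hi
    else:
        width = scheme.width
        limit = scheme.upper_cap if scheme.upper_cap is not None else hi
        lo = scheme.origin if scheme.origin is not None else float(np.floor(lo))

    if lo + width >= limit:
        warnings.warn(
            f"window width {scheme.width} spans the whole {scheme.axis} range; "
            "a single window is returned",
            stacklevel=2,
        )
        return [(lo, max(limit, lo + width) if scheme.axis != "year" else hi)]

    n = int(np.floor((limit - lo - width) / scheme.step)) + 1
    return [
        (lo + i * scheme.step, min(lo + i * scheme.step + width, limit))
        for i in range(n)
    ]


def window_trends(
    records: pd.DataFrame, scheme: WindowScheme, y: str = "rs_annual"
) -> pd.DataFrame:
    """Per-window trend of Rs versus year.

    Returns one row per window with bounds, n, OLS slope/p/SE, Theil–Sen
    slope, and a flag: "" (clean), "low_n" (n below ``scheme.min_n``), or
    "degenerate" (all records share one year; no slope reported). Windows
    are closed on both ends, so boundary records belong to every window
    covering them.
    """
    vals = axis_values(records, scheme.axis)
    yrs = year_of(records).astype(float).values
    resp = records[y].values.astype(float)
    rows = []
    for lo, hi in build_windows(vals, scheme):
        inside = (vals >= lo) & (vals <= hi)
        n = int(inside.sum())
        flag = ""
        slope = p = se = ts = np.nan
        if n < scheme.min_n:
            flag = "low_n"
        if n >= 2:
            try:
                t = trend(yrs[inside], resp[inside])
                slope, p, se, ts = t.slope, t.p_value, t.se_slope, t.robust_slope
            except DegenerateSeriesError:
                flag = "degenerate"
        elif not flag:
            flag = "degenerate"
        rows.append(
            {
                "axis": scheme.axis,
                "lower": lo,
                "upper": hi,
                "n": n,
                "slope": slope,
                "p_value": p,
                "se_slope": se,
                "theil_sen": ts,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
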