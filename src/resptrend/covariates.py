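"""Joining records with climate normals, anomalies, and SOC stocks.

MAT and MAP are averaged over each record's measurement window (an
18-month record gets the 18-month mean temperature and the annualized
precipitation total); anomalies are deviations from the per-cell
reference-period means; SOC comes from nearest-cell lookup with
same-ecosystem median imputation for cells missing from the grid.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr

from .errors import CovariateError

__all__ = [
    "match_climate",
    "compute_anomalies",
    "match_soc",
    "annotate_records",
    "annual_climate",
]


def _nearest_index(axis: np.ndarray, values: np.ndarray) -> np.ndarray:
    return np.abs(axis[:, None] - values[None, :]).argmin(axis=0)


def _grid_arrays(grid: xr.Dataset):
    lat = grid["lat"].values
    lon = grid["lon"].values
    years = grid["time"].dt.year.values
    t0 = int(years.min())
    temp = grid["temp"].values
    precip = grid["precip"].values
    return lat, lon, t0, len(np.unique(years)), temp, precip


def annual_climate(grid: xr.Dataset) -> xr.Dataset:
    """Per-cell annual MAT (degC) and MAP (mm/yr) series from monthly fields."""
    mat = grid["temp"].groupby("time.year").mean("time")
    map_ = grid["precip"].groupby("time.year").sum("time")
    return xr.Dataset({"mat": mat, "map": map_})


def match_climate(
    records: pd.DataFrame, grid: xr.Dataset, skip_unmatched: bool = False
) -> pd.DataFrame:
    """Attach MAT and MAP averaged over each record's measurement window.

    The window spans ``[mid_year - d/2, mid_year + d/2)`` where ``d`` is
    the record duration in years, discretized to ``round(12 d)`` months;
    the grid cell is the nearest cell centre. MAP is the window total
    scaled to an annual rate (sum * 12 / n_months).
    """
    lat_ax, lon_ax, t0, n_years, temp, precip = _grid_arrays(grid)
    n_months_total = temp.shape[0]

    ilat = _nearest_index(lat_ax, records["latitude"].values)
    ilon = _nearest_index(lon_ax, records["longitude"].values)
    dur = records["duration_years"].fillna(1.0).values
    mid = records["mid_year"].values
    n_m = np.maximum(np.round(12.0 * dur).astype(int), 1)
    start = np.round((mid - dur / 2.0 - t0) * 12.0).astype(int)

    bad = (start < 0) | (start + n_m > n_months_total)
    if bad.any():
        ids = records.loc[bad, "record_id"].tolist() if "record_id" in records else list(np.where(bad)[0])
        if not skip_unmatched:
            raise CovariateError(
                f"measurement window outside grid coverage for record(s): {ids[:10]}"
            )

    mat = np.full(len(records), np.nan)
    map_ = np.full(len(records), np.nan)
    for i in range(len(records)):
        if bad[i]:
            continue
        sl = slice(start[i], start[i] + n_m[i])
        mat[i] = temp[sl, ilat[i], ilon[i]].mean()
        map_[i] = precip[sl, ilat[i], ilon[i]].sum() * 12.0 / n_m[i]

    out = records.copy()
    out["MAT"] = mat
    out["MAP"] = map_
    return out


def compute_anomalies(
    records: pd.DataFrame,
    grid: xr.Dataset,
    reference: tuple[int, int] = (1987, 2016),
    skip_unmatched: bool = False,
) -> pd.DataFrame:
    """Attach MAT/MAP (if absent) and their anomalies dMAT/dMAP.

    The site reference means are per grid cell, averaged over all calendar
    years of ``reference``; the anomaly is the record's measurement-window
    MAT/MAP minus that reference mean.
    """
    out = records
    if "MAT" not in records.columns or "MAP" not in records.columns:
        out = match_climate(records, grid, skip_unmatched=skip_unmatched)

    ann = annual_climate(grid)
    years = ann["year"].values
    sel = (years >= reference[0]) & (years <= reference[1])
    covered = set(years[sel])
    wanted = set(range(reference[0], reference[1] + 1))
    if not wanted <= covered:
        missing = sorted(wanted - covered)
        raise CovariateError(f"grid lacks reference years {missing}")
    ref_mat = ann["mat"].values[sel].mean(axis=0)
    ref_map = ann["map"].values[sel].mean(axis=0)

    ilat = _nearest_index(grid["lat"].values, out["latitude"].values)
    ilon = _nearest_index(grid["lon"].values, out["longitude"].values)
    out = out.copy()
    out["dMAT"] = out["MAT"].values - ref_mat[ilat, ilon]
    out["dMAP"] = out["MAP"].values - ref_map[ilat, ilon]
    return out


def match_soc(records: pd.DataFrame, soc_grid: xr.DataArray) -> pd.DataFrame:
    """Attach topsoil SOC stock by nearest-cell lookup.

    Records whose cell is missing get the median SOC of non-missing
    records from the same ecosystem, with ``soc_imputed=True``; an
    ecosystem with no non-missing values raises :class:`CovariateError`.
    """
    ilat = _nearest_index(soc_grid["lat"].values, records["latitude"].values)
    ilon = _nearest_index(soc_grid["lon"].values, records["longitude"].values)
    soc = soc_grid.values[ilat, ilon]
    out = records.copy()
    out["soc"] = soc
    out["soc_imputed"] = np.isnan(soc)

    if out["soc_imputed"].any():
        eco_col = "ecosystem" if "ecosystem" in out.columns else None
        if eco_col is None:
            med = out["soc"].median()
            if np.isnan(med):
                raise CovariateError("no non-missing SOC values to impute from")
            out.loc[out["soc_imputed"], "soc"] = med
        else:
            medians = out.groupby(eco_col)["soc"].median()
            for eco, sub in out[out["soc_imputed"]].groupby(eco_col):
                med = medians.get(eco, np.nan)
                if np.isnan(med):
                    raise CovariateError(
                        f"ecosystem {eco!r} has no non-missing SOC values to impute from"
                    )
                out.loc[sub.index, "soc"] = med
    return out


def annotate_records(
    records: pd.DataFrame,
    grid: xr.Dataset,
    soc_grid: Optional[xr.DataArray] = None,
    reference: tuple[int, int] = (1987, 2016),
    skip_unmatched: bool = False,
) -> pd.DataFrame:
    """Full annotation: MAT/MAP, dMAT/dMAP, and (optionally) SOC.

    Never drops records; matching failures raise unless
    ``skip_unmatched`` is set, in which case unmatched records carry NaN.
    """
    out = compute_anomalies(records, grid, reference, skip_unmatched=skip_unmatched)
    if soc_grid is not None:
        out = match_soc(out, soc_grid)
    return out
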