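"""Square-root climate model, AIC term selection, and Monte Carlo
upscaling of annual global soil respiration from gridded climate.

The point-record model regresses sqrt(Rs) on MAT, MAP, their squares,
MAT x MAP, and the normal-anomaly interactions MAT x dMAT and
MAP x dMAP; stepwise AIC selection (both directions, marginality
respected) prunes terms. Uncertainty is propagated by sampling model
coefficients from their fitted distributions, predicting per-cell annual
Rs on a land-masked climate grid, and area-weighting to a global total
in Pg C per year for each Monte Carlo trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
import scipy.stats
import statsmodels.api as sm
import xarray as xr

from .covariates import annual_climate
from .errors import ConfigurationError, ModelError

__all__ = [
    "EQ_TERMS",
    "ClimateModelFit",
    "GlobalRsSeries",
    "fit_climate_model",
    "sample_parameters",
    "cell_area",
    "predict_global_rs",
    "trend_periods",
]

EARTH_RADIUS_KM = 6371.0

#: Candidate terms of the climate model for sqrt(Rs), in entry order.
EQ_TERMS = [
    "MAT",
    "I(MAT ** 2)",
    "MAP",
    "I(MAP ** 2)",
    "MAT:MAP",
    "MAT:dMAT",
    "MAP:dMAP",
]

#: Marginality: a term may only stay in the model while its prerequisites do.
#: (The anomaly terms enter only through interactions, so they require just
#: the corresponding climate normal.)
_REQUIRES = {
    "I(MAT ** 2)": ["MAT"],
    "I(MAP ** 2)": ["MAP"],
    "MAT:MAP": ["MAT", "MAP"],
    "MAT:dMAT": ["MAT"],
    "MAP:dMAP": ["MAP"],
}


@dataclass
class ClimateModelFit:
    """Selected terms with coefficient means, SEs and covariance."""

    terms: list[str]  # without the intercept
    params: pd.Series  # includes "Intercept"
    bse: pd.Series
    cov: pd.DataFrame
    aic: float
    n: int


@dataclass
class GlobalRsSeries:
    """Per-year global Rs (Pg C/yr): Monte Carlo mean, SD, and raw trials."""

    years: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    trials: np.ndarray  # (n_trials, n_years)
    n_clamped: int = 0  # negative sqrt-scale predictions clamped to zero


def _ols(records: pd.DataFrame, terms: Sequence[str]):
    rhs = " + ".join(terms) if terms else "1"
    y, x = patsy.dmatrices(f"np.sqrt(rs_annual) ~ {rhs}", records,
                           return_type="dataframe")
    return sm.OLS(y.values.ravel(), x.values).fit(), list(x.columns)


def fit_climate_model(
    records: pd.DataFrame,
    stepwise: bool = True,
    candidates: Sequence[str] = EQ_TERMS,
) -> ClimateModelFit:
    """Fit sqrt(Rs) on the climate design, optionally with AIC selection.

    Stepwise selection starts from the full candidate model and at each
    iteration applies the single add/drop move (respecting marginality)
    that lowers AIC most, until no move improves it.
    """
    for col in ("rs_annual", "MAT", "MAP", "dMAT", "dMAP"):
        if col not in records.columns:
            raise ModelError(f"records lack required column {col!r}")
    if (records["rs_annual"] < 0).any():
        raise ModelError("negative Rs value: square-root response undefined")

    def score(fit_res, k: int) -> tuple:
        # an exact (zero-residual) fit makes AIC degenerate; rank all such
        # fits equal and break the tie by parsimony
        tss = float(fit_res.centered_tss) or 1.0
        if fit_res.ssr <= 1e-12 * tss:
            return (-np.inf, k)
        return (float(fit_res.aic), k)

    current = list(candidates)
    fit, names = _ols(records, current)
    if stepwise:
        while True:
            best = (score(fit, len(current)), None, None)
            # drops: a term is removable if nothing retained requires it
            for t in current:
                if any(t in _REQUIRES.get(u, []) for u in current if u != t):
                    continue
                trial = [u for u in current if u != t]
                f, _ = _ols(records, trial)
                if score(f, len(trial)) < best[0]:
                    best = (score(f, len(trial)), "drop", t)
            # adds: a candidate may enter if its prerequisites are present
            for t in candidates:
                if t in current:
                    continue
                if not all(r in current for r in _REQUIRES.get(t, [])):
                    continue
                trial = current + [t]
                f, _ = _ols(records, trial)
                if score(f, len(trial)) < best[0]:
                    best = (score(f, len(trial)), "add", t)
            if best[1] is None:
                break
            if best[1] == "drop":
                current = [u for u in current if u != best[2]]
            else:
                current = current + [best[2]]
            # keep candidate entry order
            current = [t for t in candidates if t in current]
            fit, names = _ols(records, current)

    params = pd.Series(fit.params, index=names)
    bse = pd.Series(fit.bse, index=names)
    cov = pd.DataFrame(fit.cov_params(), index=names, columns=names)
    return ClimateModelFit(
        terms=current, params=params, bse=bse, cov=cov,
        aic=float(fit.aic), n=int(fit.nobs),
    )


def sample_parameters(
    fit: ClimateModelFit,
    n_trials: int = 1000,
    seed: int = 0,
    correlated: bool = False,
) -> pd.DataFrame:
    """Monte Carlo coefficient draws, one row per trial.

    By default each coefficient is drawn independently from
    normal(mean, SE); ``correlated=True`` instead samples from the joint
    multivariate normal with the fitted coefficient covariance (tighter
    when coefficients covary).
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    if not np.all(np.isfinite(fit.bse.values)):
        raise ModelError("non-finite coefficient standard errors")
    rng = np.random.default_rng(seed)
    if correlated:
        draws = rng.multivariate_normal(
            fit.params.values, fit.cov.values, size=n_trials,
            method="cholesky" if _is_pd(fit.cov.values) else "svd",
        )
    else:
        draws = fit.params.values + fit.bse.values * rng.standard_normal(
            (n_trials, len(fit.params))
        )
    return pd.DataFrame(draws, columns=fit.params.index)


def _is_pd(a: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(a)
        return True
    except np.linalg.LinAlgError:
        return False


def cell_area(
    lat_upper: np.ndarray,
    resolution: float,
    mode: str = "paper",
    radius_km: float = EARTH_RADIUS_KM,
) -> np.ndarray:
    """Grid-cell area in km^2 for cells whose upper edge is ``lat_upper``.

    "paper" mode evaluates the cosine at the cell's upper latitude
    boundary, A = R^2 dlon dlat cos(lat_upper); "exact" mode integrates
    the spherical band, A = R^2 dlon (sin(lat_upper) - sin(lat_lower)).
    The paper-mode hemispheric biases cancel in a global sum.
    """
    lat_upper = np.asarray(lat_upper, dtype=float)
    d = np.deg2rad(resolution)
    if mode == "paper":
        return radius_km**2 * d * d * np.cos(np.deg2rad(lat_upper))
    if mode == "exact":
        lo = np.deg2rad(lat_upper - resolution)
        return radius_km**2 * d * (np.sin(np.deg2rad(lat_upper)) - np.sin(lo))
    raise ConfigurationError(f"unknown area mode {mode!r}")


def _design_columns(names: Sequence[str], mat, map_, dmat, dmap) -> np.ndarray:
    """Evaluate the selected design columns on flattened grid arrays."""
    funcs = {
        "Intercept": lambda: np.ones_like(mat),
        "MAT": lambda: mat,
        "I(MAT ** 2)": lambda: mat**2,
        "MAP": lambda: map_,
        "I(MAP ** 2)": lambda: map_**2,
        "MAT:MAP": lambda: mat * map_,
        "MAT:dMAT": lambda: mat * dmat,
        "MAP:dMAP": lambda: map_ * dmap,
    }
    cols = []
    for name in names:
        if name not in funcs:
            raise ModelError(f"cannot evaluate model term {name!r} on the grid")
        cols.append(funcs[name]())
    return np.column_stack(cols)


def predict_global_rs(
    draws: pd.DataFrame,
    grid: xr.Dataset,
    land_mask: xr.DataArray,
    years: Optional[Sequence[int]] = None,
    reference: tuple[int, int] = (1987, 2016),
    area_mode: str = "paper",
) -> GlobalRsSeries:
    """Annual global Rs (Pg C/yr) per Monte Carlo trial.

    For each trial and year the sqrt-scale linear predictor is evaluated
    per land cell from that year's MAT/MAP and their anomalies relative
    to the per-cell reference-period means, clamped at zero (a negative
    predictor means zero flux, not negative flux), squared to g C m-2
    yr-1, multiplied by cell area and summed over land:
    g C m-2 x km^2 x 1e6 m^2/km^2 x 1e-15 Pg/g = Pg C.
    """
    if land_mask.shape != (grid.sizes["lat"], grid.sizes["lon"]):
        raise ConfigurationError("land mask shape does not match the grid")
    ann = annual_climate(grid)
    all_years = ann["year"].values
    if years is None:
        years = all_years
    years = np.asarray(sorted(years), dtype=int)

    sel = (all_years >= reference[0]) & (all_years <= reference[1])
    ref_mat = ann["mat"].values[sel].mean(axis=0)
    ref_map = ann["map"].values[sel].mean(axis=0)

    mask = land_mask.values.astype(bool)
    lat = grid["lat"].values
    res = float(grid.attrs.get("resolution", abs(lat[1] - lat[0])))
    upper = lat + res / 2.0
    area_km2 = np.broadcast_to(
        cell_area(upper, res, mode=area_mode)[:, None], mask.shape
    )[mask]
    area_m2 = area_km2 * 1e6

    beta = draws.values  # (n_trials, p)
    names = list(draws.columns)
    n_trials = beta.shape[0]
    trials = np.empty((n_trials, len(years)))
    n_clamped = 0
    year_index = {int(y): i for i, y in enumerate(all_years)}
    for j, y in enumerate(years):
        iy = year_index[int(y)]
        mat = ann["mat"].values[iy][mask]
        map_ = ann["map"].values[iy][mask]
        dmat = mat - ref_mat[mask]
        dmap = map_ - ref_map[mask]
        x = _design_columns(names, mat, map_, dmat, dmap)  # (cells, p)
        eta = x @ beta.T  # (cells, n_trials)
        n_clamped += int((eta < 0).sum())
        np.clip(eta, 0.0, None, out=eta)
        rs = eta**2  # g C m-2 yr-1
        trials[:, j] = (rs * area_m2[:, None]).sum(axis=0) * 1e-15
    return GlobalRsSeries(
        years=years,
        mean=trials.mean(axis=0),
        sd=trials.std(axis=0, ddof=0),
        trials=trials,
        n_clamped=n_clamped,
    )


def trend_periods(
    series: GlobalRsSeries, periods: Sequence[tuple[int, int]]
) -> pd.DataFrame:
    """Pooled trend of global Rs over each period.

    All (trial, year) points in the period enter one regression, so the
    residual df is n_years x n_trials - 2 (e.g. 12 years x 1000 trials
    gives df = 11,998). Zero-variance trials with an exact linear series
    are reported with infinite t and p = 0.
    """
    rows = []
    for a, b in periods:
        inside = (series.years >= a) & (series.years <= b)
        if not inside.any() or series.years.min() > a or series.years.max() < b:
            raise ConfigurationError(f"period {a}-{b} outside the series years")
        yrs = series.years[inside]
        vals = series.trials[:, inside]
        x = np.tile(yrs.astype(float), vals.shape[0])
        yv = vals.ravel()
        n = len(x)
        slope, intercept = np.polyfit(x, yv, 1)
        resid = yv - (slope * x + intercept)
        dof = n - 2
        sxx = ((x - x.mean()) ** 2).sum()
        rss = (resid**2).sum()
        if rss <= 1e-18 * (yv**2).sum():  # numerically exact line
            rss = 0.0
        s2 = rss / dof
        if s2 > 0:
            se = np.sqrt(s2 / sxx)
            t = slope / se
            p = 2 * scipy.stats.t.sf(abs(t), dof)
        else:
            se, t, p = 0.0, np.inf if slope != 0 else 0.0, 0.0
        rows.append(
            {
                "period": f"{a}-{b}",
                "slope": slope,
                "se": se,
                "t": t,
                "df": dof,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
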