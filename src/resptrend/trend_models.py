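"""Weighted linear model with sequential (Type I) ANOVA, simple period
trends, and the Theil–Sen robust slope.

The interaction model regresses annual Rs on year (linear and quadratic),
measurement method, geography, ecosystem descriptors, SOC stock and
climate covariates, weighted by each record's years of measurement. The
ANOVA attributes weighted sums of squares to terms sequentially in design
order, so term order matters and is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .errors import DegenerateSeriesError, ModelError

__all__ = [
    "ModelSpec",
    "FitResult",
    "TrendResult",
    "fit_weighted_lm",
    "trend",
    "theil_sen",
    "rs_model_terms",
    "prepare_model_frame",
]


@dataclass
class ModelSpec:
    """Response, ordered model terms, and the weight column (or None)."""

    response: str
    terms: Sequence[str]
    weights: Optional[str] = None

    @property
    def formula(self) -> str:
        return f"{self.response} ~ {' + '.join(self.terms)}"


@dataclass
class FitResult:
    """Coefficients, standard errors, and the sequential ANOVA table."""

    params: pd.Series
    bse: pd.Series
    df_resid: int
    anova: pd.DataFrame  # columns: term, df, ss, F, p
    rss: float
    total_ss: float
    weights: Optional[str] = None
    formula: str = ""


@dataclass
class TrendResult:
    """OLS slope of a response against a single covariate plus robust slope."""

    slope: float
    intercept: float
    p_value: float
    n: int
    se_slope: float
    robust_slope: float


def theil_sen(x: np.ndarray, y: np.ndarray) -> float:
    """Theil–Sen slope: the median of all pairwise slopes.

    Requires at least two points with distinct x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(np.unique(x)) < 2:
        raise DegenerateSeriesError("Theil–Sen needs >=2 points with distinct x")
    slope, _, _, _ = scipy.stats.theilslopes(y, x)
    return float(slope)


def trend(
    x: np.ndarray, y: np.ndarray, min_n_for_p: int = 3
) -> TrendResult:
    """OLS slope/intercept/two-sided p plus the Theil–Sen robust slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or len(np.unique(x)) < 2:
        raise DegenerateSeriesError("trend needs >=2 points with distinct x")
    res = scipy.stats.linregress(x, y)
    p = float(res.pvalue) if len(x) >= min_n_for_p else np.nan
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=p,
        n=int(len(x)),
        se_slope=float(res.stderr),
        robust_slope=theil_sen(x, y),
    )


def rs_model_terms(
    include_partition: bool = False,
    soc: str = "soc",
    year: str = "year_c",
) -> list[str]:
    """Terms of the full Rs interaction model, in entry order.

    Year enters linearly and quadratically and interacts with method,
    latitude, altitude, stage, ecosystem, SOC and biome; climate normals
    and anomalies interact with biome. For partitioned fluxes (Rh/Ra) the
    year x partitioning-method interaction is added.
    """
    t = [
        year,
        f"I({year} ** 2)",
        "meas_method",
        "latitude",
        "elevation",
        "stage",
        "ecosystem",
        soc,
        "biome",
        "MAT",
        "MAP",
        "dMAT",
        "dMAP",
        f"{year}:meas_method",
        f"{year}:latitude",
        f"{year}:elevation",
        f"{year}:stage",
        f"{year}:ecosystem",
        f"{year}:{soc}",
        f"{year}:biome",
        "MAT:MAP",
        "MAT:biome",
        "MAP:biome",
        "dMAT:dMAP",
        "dMAT:biome",
        "dMAP:biome",
        "MAT:MAP:biome",
        "dMAT:dMAP:biome",
    ]
    if include_partition:
        t.insert(13, "partition_method")
        t.append(f"{year}:partition_method")
    return t


def prepare_model_frame(
    records: pd.DataFrame,
    base_year: int = 1987,
    factor_cols: Sequence[str] = ("meas_method", "stage", "ecosystem", "biome",
                                  "partition_method"),
    min_level_n: int = 2,
) -> pd.DataFrame:
    """Model frame with centred year and merged rare factor levels.

    Year is centred at ``base_year`` before squaring (conditioning only;
    F tests are unaffected). Factor levels observed fewer than
    ``min_level_n`` times are merged into "other" rather than erroring.
    """
    df = records.copy()
    df["year"] = np.floor(df["mid_year"]).astype(int)
    df["year_c"] = df["year"] - base_year
    for col in factor_cols:
        if col not in df.columns:
            continue
        s = df[col].astype(str)
        counts = s.value_counts()
        rare = counts[counts < min_level_n].index
        if len(rare):
            import warnings

            warnings.warn(
                f"merging rare level(s) of {col!r} into 'other': {sorted(rare)}",
                stacklevel=2,
            )
            s = s.where(~s.isin(rare), "other")
            # a merged bucket that is still rare is absorbed into the mode
            if (s == "other").sum() < min_level_n:
                s = s.where(s != "other", counts.index[0])
        df[col] = s
    return df


def _aliased_columns(xw: np.ndarray, names: Sequence[str]) -> list[str]:
    _, r, piv = scipy.linalg.qr(xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(xw.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def fit_weighted_lm(records: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Weighted least squares with a sequential (Type I) ANOVA table.

    Categorical factors are treatment-coded with the first level as the
    reference; the ANOVA decomposes the weighted total sum of squares
    over terms in design order (main effects before interactions, the
    convention of R model formulas), so the per-term SS depend on that
    order while their total does not.
    """
    y_mat, x_mat = patsy.dmatrices(spec.formula, records, return_type="dataframe")
    y = y_mat.values.ravel()
    design_info = x_mat.design_info
    names = list(x_mat.columns)

    if spec.weights is None:
        w = np.ones(len(y))
    else:
        w = np.asarray(records.loc[x_mat.index, spec.weights], dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ModelError(f"non-positive or missing weight in {spec.weights!r}")

    sw = np.sqrt(w)
    xw = x_mat.values * sw[:, None]
    yw = y * sw
    rank = np.linalg.matrix_rank(xw)
    if rank < xw.shape[1]:
        aliased = _aliased_columns(xw, names)
        raise ModelError(f"rank-deficient design; aliased column(s): {aliased}")

    wls = sm.WLS(y, x_mat.values, weights=w).fit()
    params = pd.Series(wls.params, index=names)
    bse = pd.Series(wls.bse, index=names)

    # sequential decomposition: add one term block at a time, in order
    term_names = design_info.term_names
    slices = [design_info.term_slices[t] for t in design_info.terms]
    has_intercept = term_names and term_names[0] == "Intercept"

    def rss_of(cols: int) -> float:
        if cols == 0:
            return float(yw @ yw)
        beta, _, _, _ = np.linalg.lstsq(xw[:, :cols], yw, rcond=None)
        resid = yw - xw[:, :cols] @ beta
        return float(resid @ resid)

    rows = []
    start = 1 if has_intercept else 0
    prev_cols = slices[start - 1].stop if has_intercept else 0
    prev_rss = rss_of(prev_cols)
    total_ss = prev_rss  # weighted SS about the (weighted) mean
    for t_name, sl in zip(term_names[start:], slices[start:]):
        cur_rss = rss_of(sl.stop)
        rows.append((t_name, sl.stop - sl.start, prev_rss - cur_rss))
        prev_cols, prev_rss = sl.stop, cur_rss

    rss = prev_rss
    df_resid = len(y) - xw.shape[1]
    if df_resid <= 0:
        raise ModelError("no residual degrees of freedom")
    mse = rss / df_resid
    anova = pd.DataFrame(rows, columns=["term", "df", "ss"])
    anova["F"] = (anova["ss"] / anova["df"]) / mse
    anova["p"] = scipy.stats.f.sf(anova["F"], anova["df"], df_resid)

    return FitResult(
        params=params,
        bse=bse,
        df_resid=df_resid,
        anova=anova,
        rss=rss,
        total_ss=total_ss,
        weights=spec.weights,
        formula=spec.formula,
    )
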