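"""Regression engines: Theil–Sen vs brute force, WLS vs normal equations,
sequential ANOVA conservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resptrend.errors import DegenerateSeriesError, ModelError
from resptrend.trend_models import (
    ModelSpec,
    fit_weighted_lm,
    prepare_model_frame,
    rs_model_terms,
    theil_sen,
    trend,
)


def brute_force_theil_sen(x, y):
    """Independent oracle: enumerate every pairwise slope, take the median."""
    slopes = []
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if x[j] != x[i]:
                slopes.append((y[j] - y[i]) / (x[j] - x[i]))
    return float(np.median(slopes))


class TestTheilSen:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([0, 1, 2], [0, 1, 2], 1.0),
            ([1, 2, 3], [1, 2, 10], 4.5),  # pairwise slopes {1, 4.5, 8}
            ([1, 2, 3, 4], [5, 5, 5, 5], 0.0),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert theil_sen(x, y) == pytest.approx(expected)

    def test_rejects_degenerate_x(self):
        with pytest.raises(DegenerateSeriesError):
            theil_sen([2, 2, 2], [1, 2, 3])

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 200))
        x = rng.normal(size=n)
        y = 2.0 * x + rng.normal(size=n)
        assert theil_sen(x, y) == pytest.approx(brute_force_theil_sen(x, y),
                                                rel=1e-12, abs=1e-12)

    def test_breakdown_resistance_to_contamination(self):
        """<29% wild outliers perturb the slope by less than half its size."""
        rng = np.random.default_rng(4)
        n = 50
        x = np.arange(n, dtype=float)
        y = 3.0 * x + rng.normal(0, 0.5, n)
        y_bad = y.copy()
        idx = rng.choice(n, size=14, replace=False)  # 28%
        y_bad[idx] += rng.normal(0, 500, 14)
        assert abs(theil_sen(x, y_bad) - 3.0) < 0.5 * 3.0


class TestTrend:
    def test_exact_line(self):
        t = trend([1987, 1988, 1989], [100, 110, 120])
        assert t.slope == pytest.approx(10.0)
        assert t.robust_slope == pytest.approx(10.0)
        assert np.isfinite(t.p_value)

    def test_built_in_early_slope_recovered(self):
        from conftest import clean_config
        from resptrend.srdb_ingest import read_srdb, year_of
        from resptrend.synthetic_data import generate_climate_grid, generate_records

        cfg = clean_config(slope_early=27.66, slope_late=0.0)
        rec, _ = generate_records(cfg, generate_climate_grid(cfg))
        df = read_srdb(rec)
        pre = df[year_of(df) < 2000]
        t = trend(year_of(pre).astype(float).values, pre["rs_annual"].values)
        assert t.slope == pytest.approx(27.66, abs=1e-9)

    def test_degenerate_x_raises(self):
        with pytest.raises(DegenerateSeriesError):
            trend([5, 5, 5], [1, 2, 3])


def wls_normal_equations(X, y, w):
    """Independent oracle: explicit weighted normal-equations solve."""
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    return beta


class TestWeightedLm:
    def test_two_group_anova_oracle(self):
        # hand oracle: groups {1,2,3} vs {4,5,6}: SSB = 13.5, SSW = 4 on
        # 4 df -> F = 13.5 / 1 = 13.5
        df = pd.DataFrame(
            {"value": [1, 2, 3, 4, 5, 6.0],
             "group": ["a", "a", "a", "b", "b", "b"]}
        )
        fit = fit_weighted_lm(df, ModelSpec("value", ["group"]))
        row = fit.anova.iloc[0]
        assert row["df"] == 1
        assert row["F"] == pytest.approx(13.5)
        assert fit.df_resid == 4

    def test_equal_weights_match_ols(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"y": rng.normal(size=40), "x": rng.normal(size=40),
             "w": np.full(40, 3.0)}
        )
        unweighted = fit_weighted_lm(df, ModelSpec("y", ["x"]))
        weighted = fit_weighted_lm(df, ModelSpec("y", ["x"], weights="w"))
        assert np.allclose(unweighted.params, weighted.params)

    def test_noise_free_coefficients_recovered(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": 2.0 + 1.5 * x1 - 0.7 * x2})
        fit = fit_weighted_lm(df, ModelSpec("y", ["x1", "x2"]))
        assert fit.params.values == pytest.approx([2.0, 1.5, -0.7], abs=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        df = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "g": rng.choice(["u", "v", "w"], size=n),
                "w": rng.uniform(0.5, 4.0, size=n),
            }
        )
        spec = ModelSpec("y", ["x1", "g", "x2", "x1:g"], weights="w")
        fit = fit_weighted_lm(df, spec)
        import patsy

        _, X = patsy.dmatrices(spec.formula, df, return_type="dataframe")
        beta = wls_normal_equations(X.values, df["y"].values, df["w"].values)
        assert np.allclose(fit.params.values, beta, rtol=1e-8)

    def test_sequential_ss_sums_to_total(self, parsed_records, climate_grid,
                                         soc_grid):
        from resptrend.covariates import annotate_records
        from resptrend.srdb_ingest import apply_filters

        filtered, _ = apply_filters(parsed_records)
        ann = annotate_records(filtered, climate_grid, soc_grid=soc_grid,
                               skip_unmatched=True)
        frame = prepare_model_frame(ann, min_level_n=12).dropna(
            subset=["MAT", "MAP", "dMAT", "dMAP", "soc"])
        spec = ModelSpec("rs_annual", rs_model_terms(), weights="duration_years")
        fit = fit_weighted_lm(frame, spec)
        assert fit.anova["ss"].sum() + fit.rss == pytest.approx(
            fit.total_ss, rel=1e-6)

    def test_type1_order_sensitivity_preserves_total(self):
        rng = np.random.default_rng(5)
        n = 80
        x1 = rng.normal(size=n)
        x2 = 0.8 * x1 + 0.6 * rng.normal(size=n)  # correlated regressors
        df = pd.DataFrame({"x1": x1, "x2": x2,
                           "y": x1 + x2 + rng.normal(size=n)})
        f12 = fit_weighted_lm(df, ModelSpec("y", ["x1", "x2"]))
        f21 = fit_weighted_lm(df, ModelSpec("y", ["x2", "x1"]))
        ss12 = dict(zip(f12.anova["term"], f12.anova["ss"]))
        ss21 = dict(zip(f21.anova["term"], f21.anova["ss"]))
        assert ss12["x1"] != pytest.approx(ss21["x1"], rel=1e-3)
        assert f12.anova["ss"].sum() == pytest.approx(f21.anova["ss"].sum())

    def test_rank_deficient_design_names_alias(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "z": [2.0, 4, 6, 8],
                           "y": [1.0, 2, 3, 4]})
        with pytest.raises(ModelError, match="aliased"):
            fit_weighted_lm(df, ModelSpec("y", ["x", "z"]))

    def test_nonpositive_weight_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2, 3], "x": [1.0, 2, 4],
                           "w": [1.0, 0.0, 1.0]})
        with pytest.raises(ModelError, match="weight"):
            fit_weighted_lm(df, ModelSpec("y", ["x"], weights="w"))


def test_rare_factor_levels_merged_with_warning():
    df = pd.DataFrame(
        {
            "mid_year": [2000.5] * 12,
            "biome": ["Temperate"] * 8 + ["Boreal"] * 3 + ["Arctic"],
        }
    )
    with pytest.warns(UserWarning, match="Arctic"):
        out = prepare_model_frame(df, min_level_n=2,
                                  factor_cols=("biome",))
    assert "Arctic" not in set(out["biome"])
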