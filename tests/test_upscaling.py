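"""Climate-model recovery, parameter sampling, areas, and global totals."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from resptrend.errors import ConfigurationError, ModelError
from resptrend.synthetic_data import (
    generate_climate_grid,
    generate_land_mask,
    generate_sqrt_climate_records,
)
from resptrend.upscaling import (
    ClimateModelFit,
    cell_area,
    fit_climate_model,
    predict_global_rs,
    sample_parameters,
    trend_periods,
    GlobalRsSeries,
)

from conftest import clean_config


class TestFitClimateModel:
    def test_noise_free_single_term_recovered(self):
        rng = np.random.default_rng(0)
        mat = rng.uniform(-5, 25, 400)
        df = pd.DataFrame(
            {
                "MAT": mat,
                "MAP": rng.uniform(200, 2000, 400),
                "dMAT": rng.normal(0, 0.5, 400),
                "dMAP": rng.normal(0, 50, 400),
                "rs_annual": (2.0 + 0.3 * mat) ** 2,
            }
        )
        # keep MAT positive-effect domain so sqrt is exact
        df = df[2.0 + 0.3 * df["MAT"] > 0]
        fit = fit_climate_model(df)
        assert fit.terms == ["MAT"]
        assert fit.params["Intercept"] == pytest.approx(2.0, abs=1e-8)
        assert fit.params["MAT"] == pytest.approx(0.3, abs=1e-8)

    def test_negative_rs_is_domain_error(self):
        df = pd.DataFrame(
            {"MAT": [1.0, 2], "MAP": [500.0, 600], "dMAT": [0.0, 0],
             "dMAP": [0.0, 0], "rs_annual": [100.0, -5.0]}
        )
        with pytest.raises(ModelError, match="negative"):
            fit_climate_model(df)

    def test_marginality_main_effects_kept_with_interaction(self):
        cfg = clean_config(grid_resolution=15.0)
        grid = generate_climate_grid(cfg)
        coef = {"Intercept": 5.0, "MAT": 0.4, "MAT:MAP": 2e-4}
        rec = generate_sqrt_climate_records(cfg, grid, coef, n_records=1500,
                                            sd_sqrt=1.0)
        fit = fit_climate_model(rec)
        if "MAT:MAP" in fit.terms:
            assert {"MAT", "MAP"} <= set(fit.terms)

    def test_pure_noise_covariate_rejected_by_aic(self):
        """A covariate unrelated to the response is dropped by stepwise AIC
        at close to the theoretical rate P(chi2_1 < 2) ~ 0.84.

        The intercept is large enough that no sqrt-scale prediction clips
        at zero, so the linear truth lies inside the candidate family.
        """
        rejected = 0
        n_reps = 20
        for s in range(n_reps):
            cfg = clean_config(grid_resolution=15.0, seed=50 + s)
            grid = generate_climate_grid(cfg)
            coef = {"Intercept": 15.0, "MAT": 0.5}
            rec = generate_sqrt_climate_records(cfg, grid, coef,
                                                n_records=5000, sd_sqrt=1.0)
            rng = np.random.default_rng(900 + s)
            rec["noise_cov"] = rng.normal(size=len(rec))
            fit = fit_climate_model(
                rec, candidates=["MAT", "noise_cov"])
            assert "MAT" in fit.terms
            rejected += "noise_cov" not in fit.terms
        assert rejected >= 0.7 * n_reps


class TestSampleParameters:
    def _fit(self, se=0.0):
        idx = ["Intercept", "MAT"]
        return ClimateModelFit(
            terms=["MAT"],
            params=pd.Series([10.0, 0.5], index=idx),
            bse=pd.Series([se, se], index=idx),
            cov=pd.DataFrame(np.eye(2) * se**2, index=idx, columns=idx),
            aic=0.0,
            n=100,
        )

    def test_zero_se_draws_are_the_mean(self):
        draws = sample_parameters(self._fit(se=0.0), n_trials=50, seed=1)
        assert (draws["Intercept"] == 10.0).all()
        assert (draws["MAT"] == 0.5).all()

    def test_sample_mean_within_clt_band(self):
        draws = sample_parameters(self._fit(se=2.0), n_trials=4000, seed=3)
        assert abs(draws["Intercept"].mean() - 10.0) < 3 * 2.0 / np.sqrt(4000)

    def test_same_seed_identical(self):
        a = sample_parameters(self._fit(se=1.0), n_trials=20, seed=7)
        b = sample_parameters(self._fit(se=1.0), n_trials=20, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_trial_count(self):
        with pytest.raises(ConfigurationError):
            sample_parameters(self._fit(), n_trials=0)


class TestCellArea:
    def test_paper_mode_formula(self):
        a = cell_area(np.array([0.5]), 0.5, mode="paper")[0]
        d = np.deg2rad(0.5)
        assert a == pytest.approx(6371.0**2 * d * d * np.cos(np.deg2rad(0.5)))

    def test_exact_mode_conserves_sphere(self):
        res = 0.5
        uppers = np.arange(-90 + res, 90 + res / 2, res)
        total = cell_area(uppers, res, mode="exact").sum() * (360 / res)
        assert total == pytest.approx(4 * np.pi * 6371.0**2, rel=1e-9)

    def test_paper_mode_within_point1_percent_of_exact(self):
        res = 0.5
        uppers = np.arange(-90 + res, 90 + res / 2, res)
        paper = cell_area(uppers, res, mode="paper").sum()
        exact = cell_area(uppers, res, mode="exact").sum()
        assert abs(paper - exact) / exact < 1e-3


def _tiny_world(c=10.0):
    """One land cell, constant model sqrt(Rs) = c."""
    lat = np.array([-45.0, 45.0])
    lon = np.array([-90.0, 90.0])
    time = pd.date_range("2000-01-01", "2002-12-01", freq="MS")
    shape = (len(time), 2, 2)
    grid = xr.Dataset(
        {
            "temp": (("time", "lat", "lon"), np.full(shape, 10.0)),
            "precip": (("time", "lat", "lon"), np.full(shape, 80.0)),
        },
        coords={"time": time, "lat": lat, "lon": lon},
        attrs={"resolution": 90.0},
    )
    mask = xr.DataArray([[True, False], [False, False]],
                        coords={"lat": lat, "lon": lon}, dims=("lat", "lon"))
    draws = pd.DataFrame({"Intercept": [c, c, c]})
    return grid, mask, draws


class TestPredictGlobalRs:
    def test_constant_model_closed_form(self):
        c = 10.0
        grid, mask, draws = _tiny_world(c)
        series = predict_global_rs(draws, grid, mask, reference=(2000, 2002))
        area_km2 = cell_area(np.array([0.0]), 90.0, mode="paper")[0]
        expected = c**2 * area_km2 * 1e6 * 1e-15
        assert np.allclose(series.mean, expected)
        assert np.allclose(series.sd, 0.0)

    def test_zero_se_draws_give_zero_sd(self):
        grid, mask, draws = _tiny_world()
        series = predict_global_rs(draws, grid, mask, reference=(2000, 2002))
        assert (series.sd == 0).all()

    def test_intercept_shift_increases_every_year(self):
        grid, mask, draws = _tiny_world()
        lo = predict_global_rs(draws, grid, mask, reference=(2000, 2002))
        hi = predict_global_rs(draws + 1.0, grid, mask, reference=(2000, 2002))
        assert (hi.trials > lo.trials).all()

    def test_mask_shape_mismatch_rejected(self):
        grid, mask, draws = _tiny_world()
        bad = mask.isel(lat=[0])
        with pytest.raises(ConfigurationError):
            predict_global_rs(draws, grid, bad, reference=(2000, 2002))

    def test_negative_predictors_clamped_not_squared(self):
        grid, mask, _ = _tiny_world()
        draws = pd.DataFrame({"Intercept": [-5.0]})
        series = predict_global_rs(draws, grid, mask, reference=(2000, 2002))
        assert np.allclose(series.mean, 0.0)
        assert series.n_clamped > 0


class TestTrendPeriods:
    def _series(self, n_trials=1000, n_years=12, slope=0.2, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        years = np.arange(1987, 1987 + n_years)
        base = 80 + slope * (years - 1987)
        trials = base[None, :] + rng.normal(0, sd, (n_trials, n_years))
        return GlobalRsSeries(years=years, mean=trials.mean(0),
                              sd=trials.std(0), trials=trials)

    def test_df_arithmetic_for_monte_carlo_pool(self):
        s12 = self._series(n_trials=1000, n_years=12, sd=0.5)
        out = trend_periods(s12, [(1987, 1998)])
        assert out["df"].iloc[0] == 11_998
        s16 = self._series(n_trials=1000, n_years=16, sd=0.5)
        out16 = trend_periods(s16, [(1987, 2002)])
        assert out16["df"].iloc[0] == 15_998

    def test_exact_linear_zero_variance_guarded(self):
        s = self._series(n_trials=5, n_years=10, slope=0.3, sd=0.0)
        out = trend_periods(s, [(1987, 1996)])
        assert out["slope"].iloc[0] == pytest.approx(0.3)
        assert np.isinf(out["t"].iloc[0])
        assert out["p_value"].iloc[0] == 0.0

    def test_period_outside_series_rejected(self):
        s = self._series(n_years=10)
        with pytest.raises(ConfigurationError):
            trend_periods(s, [(1980, 1996)])


def test_end_to_end_recovery_against_true_model_integral():
    """Fit + upscale records born from a known model: the Monte Carlo mean
    must sit within 2 SD of the truth's closed-form grid integral."""
    cfg = clean_config(grid_resolution=10.0, seed=33)
    grid = generate_climate_grid(cfg)
    mask = generate_land_mask(cfg)
    coef = {"Intercept": 6.0, "MAT": 0.45, "MAP": 1.2e-3}
    rec = generate_sqrt_climate_records(cfg, grid, coef, n_records=4000,
                                        sd_sqrt=0.8, land_mask=mask)
    fit = fit_climate_model(rec)
    draws = sample_parameters(fit, n_trials=150, seed=9)
    series = predict_global_rs(draws, grid, mask)

    truth_draws = pd.DataFrame(
        {"Intercept": [coef["Intercept"]], "MAT": [coef["MAT"]],
         "MAP": [coef["MAP"]]}
    )
    truth = predict_global_rs(truth_draws, grid, mask)
    z = np.abs(series.mean - truth.mean) / np.maximum(series.sd, 1e-12)
    assert float(np.median(z)) < 2.0
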