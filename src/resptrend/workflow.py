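"""End-to-end pipeline orchestration from a single configuration.

A :class:`PipelineConfig` names either real input files (records CSV,
climate grid, SOC grid, land mask) or a ``synthetic`` block; the
pipeline then runs ingest -> annotation -> interaction model -> period
trends -> moving windows -> breakpoint detection -> Monte Carlo
upscaling, writing CSV/JSON outputs plus a manifest with every derived
seed, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .changepoint import detect_breakpoint
from .covariates import annotate_records
from .errors import ConfigurationError, ModelError, RespTrendError
from .moving_window import WindowScheme, window_trends
from .srdb_ingest import apply_filters, read_srdb, split_periods, year_of
from .synthetic_data import (
    SyntheticConfig,
    generate_climate_grid,
    generate_land_mask,
    generate_records,
    generate_soc_grid,
)
from .trend_models import ModelSpec, fit_weighted_lm, prepare_model_frame, rs_model_terms, trend
from .upscaling import fit_climate_model, predict_global_rs, sample_parameters, trend_periods

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "stage_seed",
           "read_climate_grid", "read_scalar_grid"]

log = logging.getLogger("resptrend")

_STAGE_IDS = {
    "synthetic": 10,
    "breakpoint": 20,
    "upscaling": 30,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive an independent per-stage seed (< 2^31) from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS.get(stage, 99)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything needed to re-run one analysis."""

    seed: int = 0
    output_dir: str = "resptrend_out"
    synthetic: Optional[dict] = None
    inputs: Optional[dict] = None  # records/climate/soc/land_mask paths
    filters: dict = field(default_factory=lambda: {"start": 1987, "end": 2016,
                                                   "sd_limit": 3.0})
    reference: tuple[int, int] = (1987, 2016)
    split_year: int = 1999
    breakpoint: dict = field(default_factory=lambda: {
        "first": 1996, "last": 2015, "n_sims": 10000,
        "mode": "slope_increments"})
    windows: list = field(default_factory=lambda: [
        {"axis": "year"}, {"axis": "latitude"}, {"axis": "soc"}])
    model: dict = field(default_factory=lambda: {"weights": "duration_years"})
    upscaling: dict = field(default_factory=lambda: {
        "trials": 1000,
        "periods": [[1987, 1998], [1999, 2014], [1987, 2016]],
        "correlated": False})

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'synthetic' or 'inputs' must be configured"
            )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    if "reference" in raw:
        raw["reference"] = tuple(raw["reference"])
    return PipelineConfig(**raw)


def read_climate_grid(path) -> xr.Dataset:
    """Climate grid from NetCDF (lat/lon/time) or long CSV
    (lat,lon,year,month,temp,precip)."""
    p = Path(path)
    if p.suffix in {".nc", ".cdf", ".netcdf"}:
        return xr.open_dataset(p, engine="scipy")
    df = pd.read_csv(p)
    df["time"] = pd.to_datetime(
        {"year": df["year"], "month": df["month"], "day": 1}
    )
    ds = df.set_index(["time", "lat", "lon"])[["temp", "precip"]].to_xarray()
    lat = ds["lat"].values
    ds.attrs["resolution"] = float(abs(lat[1] - lat[0])) if len(lat) > 1 else 0.5
    return ds


def read_scalar_grid(path, name: str) -> xr.DataArray:
    """A single lat/lon field (SOC stock or land mask) from NetCDF or CSV."""
    p = Path(path)
    if p.suffix in {".nc", ".cdf", ".netcdf"}:
        return xr.open_dataset(p, engine="scipy")[name]
    df = pd.read_csv(p)
    return df.set_index(["lat", "lon"])[name].to_xarray()


def _load_inputs(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        syn = dict(cfg.synthetic)
        syn.setdefault("seed", stage_seed(cfg.seed, "synthetic"))
        scfg = SyntheticConfig(**syn)
        grid = generate_climate_grid(scfg)
        records_raw, truth = generate_records(scfg, grid)
        soc = generate_soc_grid(scfg)
        mask = generate_land_mask(scfg)
        return records_raw, grid, soc, mask, scfg
    paths = cfg.inputs
    records_raw = pd.read_csv(paths["records"])
    grid = read_climate_grid(paths["climate"])
    soc = read_scalar_grid(paths["soc"], "soc") if paths.get("soc") else None
    mask = (
        read_scalar_grid(paths["land_mask"], "land")
        if paths.get("land_mask")
        else None
    )
    return records_raw, grid, soc, mask, None


def run_pipeline(cfg: PipelineConfig, output_dir: Optional[str] = None) -> dict:
    """Execute every stage; write outputs; return the in-memory results.

    Any stage failure is re-raised annotated with the stage name.
    """
    outdir = Path(output_dir or cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {
        "resptrend_version": __version__,
        "global_seed": cfg.seed,
        "seeds": {s: stage_seed(cfg.seed, s) for s in _STAGE_IDS},
        "config": _config_dict(cfg),
    }

    stage = "inputs"
    try:
        records_raw, grid, soc, mask, scfg = _load_inputs(cfg)
        if scfg is not None:
            manifest["synthetic_config"] = _jsonable(dataclasses.asdict(scfg))

        stage = "ingest"
        parsed = read_srdb(records_raw)
        period = (cfg.filters.get("start", 1987), cfg.filters.get("end", 2016))
        filtered, report = apply_filters(
            parsed, period=period, sd_limit=cfg.filters.get("sd_limit", 3.0)
        )
        filtered.to_csv(outdir / "filtered_records.csv", index=False)
        manifest["filter_report"] = report.to_dict()
        results["filtered"] = filtered
        results["filter_report"] = report

        stage = "annotate"
        annotated = annotate_records(
            filtered, grid, soc_grid=soc, reference=cfg.reference,
            skip_unmatched=True,
        )
        annotated.to_csv(outdir / "annotated_records.csv", index=False)
        results["annotated"] = annotated

        stage = "interaction_model"
        spec = ModelSpec(
            response="rs_annual",
            terms=rs_model_terms(),
            weights=cfg.model.get("weights", "duration_years"),
        )
        # a factor level entering k interaction terms needs >= k records;
        # escalate the rare-level merge threshold if the design is singular
        fit = None
        for min_level_n in (12, 30, 80):
            frame = prepare_model_frame(annotated, base_year=cfg.reference[0],
                                        min_level_n=min_level_n)
            frame = frame.dropna(subset=["MAT", "MAP", "dMAT", "dMAP", "soc"])
            try:
                fit = fit_weighted_lm(frame, spec)
                break
            except ModelError as exc:
                log.warning("interaction model singular at min_level_n=%d: %s",
                            min_level_n, exc)
                manifest["interaction_model_warning"] = str(exc)
        if fit is not None:
            fit.anova.to_csv(outdir / "anova_rs.csv", index=False)
            results["rs_model"] = fit

        stage = "period_trends"
        early, late = split_periods(annotated, breakpoint=cfg.split_year)
        rows = []
        for label, sub in (
            (f"{period[0]}-{period[1]}", annotated),
            (f"{period[0]}-{cfg.split_year}", early),
            (f"{cfg.split_year + 1}-{period[1]}", late),
        ):
            t = trend(year_of(sub).astype(float).values,
                      sub["rs_annual"].values)
            rows.append({"period": label, "slope": t.slope, "p_value": t.p_value,
                         "n": t.n, "se_slope": t.se_slope,
                         "theil_sen": t.robust_slope})
        trends = pd.DataFrame(rows)
        trends.to_csv(outdir / "period_trends.csv", index=False)
        results["period_trends"] = trends

        stage = "moving_windows"
        for wcfg in cfg.windows:
            scheme = WindowScheme(
                axis=wcfg["axis"],
                width=wcfg.get("width"),
                step=wcfg.get("step"),
                origin=wcfg.get("origin"),
                upper_cap=wcfg.get("upper_cap"),
                min_n=wcfg.get("min_n", 10),
            )
            table = window_trends(annotated, scheme)
            table.to_csv(outdir / f"windows_{scheme.axis}.csv", index=False)
            results[f"windows_{scheme.axis}"] = table

        stage = "breakpoint"
        bp = detect_breakpoint(
            annotated,
            candidates=range(cfg.breakpoint.get("first", 1996),
                             cfg.breakpoint.get("last", 2015) + 1),
            start=period[0],
            mode=cfg.breakpoint.get("mode", "slope_increments"),
            n_sims=cfg.breakpoint.get("n_sims", 10000),
            seed=stage_seed(cfg.seed, "breakpoint"),
        )
        bp_out = {
            "mode": bp.mode,
            "consensus": list(bp.consensus) if bp.consensus else None,
            "tests": {
                name: {
                    "statistic": res.statistic,
                    "change_position": res.change_position,
                    "years": list(pair),
                    "p_value": res.p_value,
                    "n_sims": res.n_sims,
                    "seed": res.seed,
                }
                for name, (res, pair) in bp.per_test.items()
            },
        }
        with open(outdir / "breakpoint.json", "w") as fh:
            json.dump(bp_out, fh, indent=2)
        results["breakpoint"] = bp

        stage = "upscaling"
        if mask is not None:
            clim_fit = fit_climate_model(annotated.dropna(subset=["MAT", "MAP"]))
            draws = sample_parameters(
                clim_fit,
                n_trials=cfg.upscaling.get("trials", 1000),
                seed=stage_seed(cfg.seed, "upscaling"),
                correlated=cfg.upscaling.get("correlated", False),
            )
            series = predict_global_rs(
                draws, grid, mask, reference=cfg.reference
            )
            per_year = pd.DataFrame(
                {"year": series.years, "mean_PgC": series.mean,
                 "sd_PgC": series.sd}
            )
            per_year.to_csv(outdir / "global_rs.csv", index=False)
            periods = [tuple(p) for p in cfg.upscaling.get("periods", [])]
            per_period = trend_periods(series, periods) if periods else None
            if per_period is not None:
                per_period.to_csv(outdir / "global_rs_trends.csv", index=False)
            results["climate_model"] = clim_fit
            results["global_rs"] = series
            results["global_rs_trends"] = per_period
            manifest["climate_model_terms"] = clim_fit.terms
    except RespTrendError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results


def _config_dict(cfg: PipelineConfig) -> dict:
    return _jsonable(dataclasses.asdict(cfg))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def demo_config(seed: int = 0, output_dir: str = "resptrend_demo") -> PipelineConfig:
    """A small synthetic end-to-end configuration that runs in minutes."""
    return PipelineConfig(
        seed=seed,
        output_dir=output_dir,
        synthetic={
            "n_sites": 600,
            "grid_resolution": 6.0,
            "records_per_site": 4,
        },
        breakpoint={"first": 1996, "last": 2015, "n_sims": 2000,
                    "mode": "slope_increments"},
        upscaling={"trials": 200,
                   "periods": [[1987, 1998], [1999, 2014], [1987, 2016]],
                   "correlated": False},
    )
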