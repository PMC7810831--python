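"""Seeded generators for SRDB-like record tables and climate/SOC grids.

The generators emulate the statistical structure of the real analysis
inputs — a table of annual soil-respiration (Rs) records with site
metadata, a gridded monthly temperature/precipitation time series, and a
topsoil SOC-stock grid — with fully known ground truth, so that every
downstream stage (filtering, covariate matching, trend models, moving
windows, change-point detection, upscaling) can be tested end to end
without external downloads.

Each record's flux is built as an exact sum of latent components

    Rs = base + biome offset + piecewise trend(year) + climate term + noise

and the realized components are returned in :class:`GroundTruth`, so
tests can verify the identity ``sum(components) == Rs`` and recovery of
the built-in trend slopes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ConfigurationError, EmptyResultError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_climate_grid",
    "generate_records",
    "generate_soc_grid",
    "generate_land_mask",
    "generate_sqrt_climate_records",
    "biome_of",
    "BIOME_BANDS",
]

# Absolute-latitude band edges for biome assignment (degrees).
BIOME_BANDS = {
    "Tropical": (0.0, 23.5),
    "Subtropical": (23.5, 35.0),
    "Temperate": (35.0, 55.0),  # Mediterranean carved out by longitude
    "Boreal": (55.0, 66.5),
    "Arctic": (66.5, 90.0),
}

#: Longitude box (lon_min, lon_max, abslat_min, abslat_max) relabelled
#: Mediterranean inside the temperate band.
_MEDITERRANEAN_BOX = (-10.0, 40.0, 35.0, 40.0)

_ECOSYSTEMS = ["Forest", "Grassland", "Shrubland", "Savanna", "Wetland", "Desert"]
_ECOSYSTEM_P = [0.50, 0.25, 0.10, 0.05, 0.05, 0.05]
_DURATIONS = [1.0, 1.5, 2.0, 3.0]
_DURATION_P = [0.70, 0.10, 0.10, 0.10]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Units: slopes in g C m-2 yr-2, fluxes/noise in g C m-2 yr-1,
    climate_sensitivity in g C m-2 yr-1 per degC of temperature anomaly,
    warming_rate in degC per decade, grid_resolution in degrees.
    """

    #: 600 sites x 4 records mirrors the scale of the filtered record base
    n_sites: int = 600
    years: tuple[int, int] = (1987, 2016)
    breakpoint_year: int = 2000
    slope_early: float = 27.66
    slope_late: float = 0.0
    climate_sensitivity: float = 55.0
    base_rs: float = 700.0
    biome_offsets: dict = field(
        default_factory=lambda: {
            "Tropical": 600.0,
            "Subtropical": 400.0,
            "Temperate": 100.0,
            "Mediterranean": 50.0,
            "Boreal": -150.0,
            "Arctic": -350.0,
        }
    )
    noise_sd: float = 250.0
    warming_rate: float = 0.18
    anomaly_sd: float = 0.30
    grid_resolution: float = 2.0
    records_per_site: int = 4
    #: late/early sampling-weight ratio across years; >1 reproduces the
    #: growth of the record base over time seen in community databases.
    year_density_ramp: float = 3.0
    contamination: dict = field(
        default_factory=lambda: {
            "agricultural": 0.05,
            "manipulated": 0.05,
            "non_irga_gc": 0.05,
            "missing_soc": 0.04,
        }
    )
    rh_fraction: float = 0.15
    land_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if y1 < y0:
            raise ConfigurationError(f"invalid year range {self.years}")
        res = self.grid_resolution
        if res <= 0 or (180.0 / res) % 1 or (360.0 / res) % 1:
            raise ConfigurationError(
                f"grid_resolution {res} must evenly divide 180 and 360"
            )
        for key, frac in self.contamination.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"contamination[{key}]={frac} not in [0,1]")
        for name in ("rh_fraction", "land_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} not in [0,1]")
        if self.noise_sd < 0 or self.anomaly_sd < 0:
            raise ConfigurationError("noise/anomaly SDs must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one of the named sub-streams."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class GroundTruth:
    """Realized generator state: parameters plus per-record latent components."""

    config: SyntheticConfig
    biome_bands: dict
    #: per-record latent components; base + biome_offset + trend + climate
    #: + noise reproduces the emitted Rs exactly.
    components: pd.DataFrame


def _axes(resolution: float) -> tuple[np.ndarray, np.ndarray]:
    lat = np.arange(-90.0 + resolution / 2, 90.0, resolution)
    lon = np.arange(-180.0 + resolution / 2, 180.0, resolution)
    return lat, lon


def _piecewise_trend(years: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Trend component: slope_early before the breakpoint, slope_late after.

    Continuous at the breakpoint; zero at the first configured year.
    """
    y0 = cfg.years[0]
    b = cfg.breakpoint_year
    early = cfg.slope_early * (np.minimum(years, b) - y0)
    late = cfg.slope_late * np.maximum(years - b, 0)
    return early + late


def generate_climate_grid(config: SyntheticConfig) -> xr.Dataset:
    """Monthly temperature (degC) and precipitation (mm/month) fields.

    Temperature is a latitudinal base profile plus a linear warming trend
    plus a per-(cell, year) anomaly shared by all 12 months of that year,
    plus a seasonal cycle that sums to zero over any calendar year (so
    annual means follow the trend exactly). Precipitation is positive with
    a seasonal cycle and mild multiplicative interannual noise.
    """
    lat, lon = _axes(config.grid_resolution)
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    n_years, n_lat, n_lon = len(years), len(lat), len(lon)
    months = np.arange(1, 13)

    t_base = 28.0 - 0.55 * np.abs(lat)  # degC at the cell centre
    warming = config.warming_rate / 10.0 * (years - y0)  # degC vs first year
    # seasonal cycle sums to zero over the 12 months; sign flips with hemisphere
    season = 8.0 * np.cos(2 * np.pi * (months - 6.5) / 12.0)
    hemi = np.where(lat >= 0, 1.0, -1.0)

    rng = config.rng(1)
    anom = rng.normal(0.0, config.anomaly_sd, size=(n_years, n_lat, n_lon))

    temp = (
        t_base[None, None, :, None]
        + warming[:, None, None, None]
        + anom[:, None, :, :]
        + season[None, :, None, None] * hemi[None, None, :, None]
    )  # (year, month, lat, lon)

    p_base = 30.0 + 120.0 * np.exp(-((lat / 25.0) ** 2))  # mm/month
    p_season = 1.0 + 0.4 * np.cos(2 * np.pi * (months - 0.5) / 12.0)
    p_noise = rng.gamma(shape=25.0, scale=1.0 / 25.0, size=(n_years, n_lat, n_lon))
    precip = (
        p_base[None, None, :, None]
        * p_season[None, :, None, None]
        * p_noise[:, None, :, :]
    )

    time = pd.date_range(f"{y0}-01-01", f"{y1}-12-01", freq="MS")
    shape = (n_years * 12, n_lat, n_lon)
    ds = xr.Dataset(
        {
            "temp": (("time", "lat", "lon"), temp.reshape(shape)),
            "precip": (("time", "lat", "lon"), precip.reshape(shape)),
        },
        coords={"time": time, "lat": lat, "lon": lon},
        attrs={"resolution": config.grid_resolution},
    )
    ds["temp"].attrs["units"] = "degC"
    ds["precip"].attrs["units"] = "mm/month"
    return ds


def generate_soc_grid(config: SyntheticConfig) -> xr.DataArray:
    """Topsoil (0-30 cm) SOC stock grid in Mg ha-1.

    Stocks increase toward high latitudes (carbon-rich boreal/Arctic
    soils); a configured fraction of cells is masked missing (NaN).
    """
    lat, lon = _axes(config.grid_resolution)
    rng = config.rng(2)
    soc = (
        40.0
        + 2.0 * np.abs(lat)[:, None]
        + rng.normal(0.0, 15.0, size=(len(lat), len(lon)))
    )
    soc = np.clip(soc, 1.0, None)
    frac = config.contamination.get("missing_soc", 0.0)
    if frac > 0:
        mask = rng.random(soc.shape) < frac
        soc = np.where(mask, np.nan, soc)
    da = xr.DataArray(
        soc,
        coords={"lat": lat, "lon": lon},
        dims=("lat", "lon"),
        name="soc",
        attrs={"units": "Mg ha-1", "resolution": config.grid_resolution},
    )
    return da


def generate_land_mask(config: SyntheticConfig) -> xr.DataArray:
    """Boolean land mask on the configured grid (seeded Bernoulli cells)."""
    lat, lon = _axes(config.grid_resolution)
    rng = config.rng(3)
    land = rng.random((len(lat), len(lon))) < config.land_fraction
    return xr.DataArray(
        land, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"), name="land"
    )


def biome_of(lat: float, lon: float) -> str:
    """Biome label from the latitude band (Mediterranean by longitude box)."""
    a = abs(lat)
    lo_lon, hi_lon, lo_lat, hi_lat = _MEDITERRANEAN_BOX
    if lo_lat <= a < hi_lat and lo_lon <= lon <= hi_lon:
        return "Mediterranean"
    for name, (lo, hi) in BIOME_BANDS.items():
        if lo <= a < hi or (name == "Arctic" and a >= lo):
            return name
    return "Temperate"  # pragma: no cover


def _annual_anomaly(grid: xr.Dataset, lat: np.ndarray, lon: np.ndarray,
                    years: np.ndarray) -> np.ndarray:
    """Annual-mean temperature anomaly vs the full-grid-period mean, per record."""
    temp = grid["temp"]
    annual = temp.groupby("time.year").mean("time")  # (year, lat, lon)
    ref = annual.mean("year")
    dev = annual - ref
    ilat = np.abs(grid["lat"].values[:, None] - lat[None, :]).argmin(axis=0)
    ilon = np.abs(grid["lon"].values[:, None] - lon[None, :]).argmin(axis=0)
    iyear = np.searchsorted(annual["year"].values, years)
    return dev.values[iyear, ilat, ilon]


def generate_records(
    config: SyntheticConfig, grid: xr.Dataset
) -> tuple[pd.DataFrame, GroundTruth]:
    """SRDB-dialect record table plus the realized ground truth.

    Each site contributes ``records_per_site`` annual records in distinct
    years sampled with a late-heavy weighting (``year_density_ramp``).
    Contamination flags (agricultural ecosystem, experimental manipulation,
    non-IRGA/GC method) are injected at the configured rates so that the
    ingest filters have work to do.
    """
    if config.n_sites <= 0:
        raise EmptyResultError("n_sites must be positive")
    y0, y1 = config.years
    grid_years = np.unique(grid["time"].dt.year.values)
    if grid_years.min() > y0 or grid_years.max() < y1:
        raise ConfigurationError("climate grid does not cover the configured years")

    rng = config.rng(4)
    n = config.n_sites
    site_lat = rng.uniform(-60.0, 75.0, n)
    site_lon = rng.uniform(-180.0, 180.0, n)
    site_elev = rng.uniform(0.0, 2000.0, n)
    site_eco = rng.choice(_ECOSYSTEMS, size=n, p=_ECOSYSTEM_P)
    site_stage = rng.choice(["Mature", "Aggrading"], size=n, p=[0.7, 0.3])
    site_method = rng.choice(["IRGA", "Gas chromatography"], size=n, p=[0.8, 0.2])
    site_leaf = rng.choice(["Evergreen", "Deciduous", "Mixed"], size=n)

    years_all = np.arange(y0, y1 + 1)
    ramp = config.year_density_ramp
    w = 1.0 + (ramp - 1.0) * (years_all - y0) / max(y1 - y0, 1)
    w = w / w.sum()
    k = min(config.records_per_site, len(years_all))

    rows = []
    for i in range(n):
        yrs = rng.choice(years_all, size=k, replace=False, p=w)
        for y in np.sort(yrs):
            dur = rng.choice(_DURATIONS, p=_DURATION_P)
            # centre the window inside the grid's coverage; the record's
            # calendar year is the integer part of the final mid-year
            mid = y + 0.5
            half = dur / 2.0
            mid = min(max(mid, y0 + half), y1 + 1 - half)
            rows.append((i, int(np.floor(mid)), float(mid), float(dur)))
    rec = pd.DataFrame(rows, columns=["site", "year", "mid_year", "duration"])
    m = len(rec)

    lat = site_lat[rec["site"].values]
    lon = site_lon[rec["site"].values]
    biome = np.array([biome_of(a, o) for a, o in zip(lat, lon)])
    offsets = np.array([config.biome_offsets.get(b, 0.0) for b in biome])
    trend = _piecewise_trend(rec["year"].values.astype(float), config)
    danom = _annual_anomaly(grid, lat, lon, rec["year"].values)
    climate = config.climate_sensitivity * danom
    noise = rng.normal(0.0, config.noise_sd, m) if config.noise_sd > 0 else np.zeros(m)
    det = config.base_rs + offsets + trend + climate
    # keep fluxes positive: truncate the noise draw, never the components
    noise = np.maximum(noise, 1.0 - det)
    rs = det + noise

    eco = site_eco[rec["site"].values].astype(object)
    manip = np.full(m, "None", dtype=object)
    method = site_method[rec["site"].values].astype(object)

    crng = config.rng(5)
    c = config.contamination
    eco[crng.random(m) < c.get("agricultural", 0.0)] = "Agriculture"
    manip[crng.random(m) < c.get("manipulated", 0.0)] = "N fertilization"
    method[crng.random(m) < c.get("non_irga_gc", 0.0)] = "Alkali absorption"

    rh_sites = crng.random(n) < config.rh_fraction
    is_rh = rh_sites[rec["site"].values]
    rh_share = np.clip(crng.normal(0.6, 0.05, m), 0.3, 0.9)
    rh = np.where(is_rh, rh_share * rs, np.nan)
    ra = np.where(is_rh, rs - rh_share * rs, np.nan)
    part = np.where(
        is_rh, crng.choice(["Trenching", "Isotope", "Comparison"], size=m), "None"
    )

    records = pd.DataFrame(
        {
            "Record_number": np.arange(1, m + 1),
            "Study_number": rec["site"].values + 1,
            "Latitude": lat,
            "Longitude": lon,
            "Elevation": site_elev[rec["site"].values],
            "Manipulation": manip,
            "Ecosystem_type": eco,
            "Leaf_habit": site_leaf[rec["site"].values],
            "Stage": site_stage[rec["site"].values],
            "Biome": biome,
            "Meas_method": method,
            "Partition_method": part,
            "Rs_annual": rs,
            "Rh_annual": rh,
            "Ra_annual": ra,
            "Study_midyear": rec["mid_year"].values,
            "YearsOfObs": rec["duration"].values,
        }
    )
    components = pd.DataFrame(
        {
            "record_id": records["Record_number"],
            "base": config.base_rs,
            "biome_offset": offsets,
            "trend": trend,
            "climate": climate,
            "noise": noise,
            "rs": rs,
        }
    )
    truth = GroundTruth(
        config=dataclasses.replace(config),
        biome_bands=dict(BIOME_BANDS),
        components=components,
    )
    return records, truth


def generate_sqrt_climate_records(
    config: SyntheticConfig,
    grid: xr.Dataset,
    coef: dict[str, float],
    n_records: int = 2000,
    sd_sqrt: float = 0.0,
    land_mask: Optional[xr.DataArray] = None,
) -> pd.DataFrame:
    """Records whose flux follows a known square-root climate model.

    ``coef`` maps design terms (Intercept, MAT, I(MAT**2), MAP, I(MAP**2),
    MAT:MAP, MAT:dMAT, MAP:dMAP) to true coefficients on the sqrt(Rs)
    scale; ``sd_sqrt`` is Gaussian noise added on that scale. Used to test
    recovery of the climate model and the upscaling chain.
    """
    if n_records <= 0:
        raise EmptyResultError("n_records must be positive")
    rng = config.rng(6)
    y0, y1 = config.years
    annual = grid["temp"].groupby("time.year").mean("time")
    annual_p = grid["precip"].groupby("time.year").sum("time")
    ref_t = annual.mean("year").values
    ref_p = annual_p.mean("year").values

    lat_ax, lon_ax = grid["lat"].values, grid["lon"].values
    if land_mask is not None:
        ok = np.argwhere(land_mask.values)
    else:
        ok = np.argwhere(np.ones((len(lat_ax), len(lon_ax)), dtype=bool))
    pick = ok[rng.integers(0, len(ok), n_records)]
    iy = rng.integers(0, y1 - y0 + 1, n_records)

    mat = annual.values[iy, pick[:, 0], pick[:, 1]]
    map_ = annual_p.values[iy, pick[:, 0], pick[:, 1]]
    dmat = mat - ref_t[pick[:, 0], pick[:, 1]]
    dmap = map_ - ref_p[pick[:, 0], pick[:, 1]]

    design = {
        "Intercept": np.ones(n_records),
        "MAT": mat,
        "I(MAT ** 2)": mat**2,
        "MAP": map_,
        "I(MAP ** 2)": map_**2,
        "MAT:MAP": mat * map_,
        "MAT:dMAT": mat * dmat,
        "MAP:dMAP": map_ * dmap,
    }
    eta = np.zeros(n_records)
    for term, beta in coef.items():
        if term not in design:
            raise ConfigurationError(f"unknown model term {term!r}")
        eta = eta + beta * design[term]
    if sd_sqrt > 0:
        eta = eta + rng.normal(0.0, sd_sqrt, n_records)
    rs = np.clip(eta, 0.0, None) ** 2

    return pd.DataFrame(
        {
            "record_id": np.arange(1, n_records + 1),
            "latitude": lat_ax[pick[:, 0]],
            "longitude": lon_ax[pick[:, 1]],
            "rs_annual": rs,
            "MAT": mat,
            "MAP": map_,
            "dMAT": dmat,
            "dMAP": dmap,
            "mid_year": (y0 + iy) + 0.5,
            "duration_years": 1.0,
        }
    )
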