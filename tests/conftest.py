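"""Shared fixtures: small seeded synthetic worlds for fast tests."""

import numpy as np
import pytest

from resptrend.srdb_ingest import read_srdb
from resptrend.synthetic_data import (
    SyntheticConfig,
    generate_climate_grid,
    generate_records,
    generate_soc_grid,
)

ZERO_OFFSETS = {
    b: 0.0
    for b in ["Tropical", "Subtropical", "Temperate", "Mediterranean",
              "Boreal", "Arctic"]
}
NO_CONTAMINATION = {
    "agricultural": 0.0,
    "manipulated": 0.0,
    "non_irga_gc": 0.0,
    "missing_soc": 0.0,
}


def clean_config(**kw) -> SyntheticConfig:
    """Config with every nuisance source off: pure piecewise trend."""
    base = dict(
        n_sites=80,
        grid_resolution=15.0,
        noise_sd=0.0,
        climate_sensitivity=0.0,
        anomaly_sd=0.0,
        biome_offsets=dict(ZERO_OFFSETS),
        contamination=dict(NO_CONTAMINATION),
        records_per_site=5,
        seed=11,
    )
    base.update(kw)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(n_sites=100, grid_resolution=15.0, seed=7)


@pytest.fixture(scope="session")
def climate_grid(default_config):
    return generate_climate_grid(default_config)


@pytest.fixture(scope="session")
def raw_records(default_config, climate_grid):
    records, truth = generate_records(default_config, climate_grid)
    return records, truth


@pytest.fixture(scope="session")
def parsed_records(raw_records):
    return read_srdb(raw_records[0])


@pytest.fixture(scope="session")
def soc_grid(default_config):
    return generate_soc_grid(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
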