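from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

sys.path.insert(0, str(Path(__file__).parent))

from gapmeter.raster import Raster
from gapmeter.synthetic import ScenarioConfig, generate_scenario, simulate_survey


@pytest.fixture(scope="session")
def small_scenario():
    """A 60x60 unbiased scenario with metrics, shared across tests."""
    cfg = ScenarioConfig(seed=11, width=60, height=60, n_sites=40, effort_per_site=70)
    return cfg, generate_scenario(cfg)


@pytest.fixture(scope="session")
def small_survey(small_scenario):
    cfg, scenario = small_scenario
    records, truth = simulate_survey(cfg, scenario.habitat, scenario.latent_climate, scenario.metrics)
    return records, truth


@pytest.fixture
def unit_square():
    return box(0.0, 0.0, 1.0, 1.0)


def make_raster(data, cell_size=1000.0) -> Raster:
    return Raster(np.asarray(data, dtype=float), cell_size)


@pytest.fixture
def sample_records() -> pd.DataFrame:
    rows = [
        ("Adelpha plesaure", "-23.512", "-46.701", "2001-01-01", "database"),
        ("Adelpha plesaure", "-23.512", "-46.701", "2001-01-01", "database"),  # duplicate
        ("Morpho helenor", "-23.512", "-46.701", "2001-01-01", "database"),
        ("Adelpha plesaure", "-23.512", "-46.701", "2001-01-02", "database"),
    ]
    return pd.DataFrame(rows, columns=["species", "lat", "lon", "date", "source"])
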