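"""Shared fixtures: small synthetic oceans and training tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aquasdm import (
    GridSpec,
    NicheSpec,
    PredictorStack,
    SyntheticOceanConfig,
    make_ocean,
    sample_virtual_presences,
)

SMALL_GRID = GridSpec(lon_min=120.0, lon_max=125.0, lat_min=33.0, lat_max=38.0, resolution=15.0)


@pytest.fixture(scope="session")
def small_ocean():
    """20x20 synthetic ocean; fast enough for unit tests."""
    return make_ocean(SyntheticOceanConfig(grid=SMALL_GRID, seed=11))


@pytest.fixture(scope="session")
def default_ocean():
    """The full default 40x40 ocean (shared across tests)."""
    return make_ocean(SyntheticOceanConfig())


@pytest.fixture(scope="session")
def small_presences(small_ocean):
    return sample_virtual_presences(small_ocean, NicheSpec(), n_target=120, seed=5)


def make_separable_table(n: int = 120, seed: int = 0, noise: float = 0.3) -> pd.DataFrame:
    """A labelled training table where SBT separates the classes."""
    rng = np.random.default_rng(seed)
    half = n // 2
    sbt = np.concatenate([rng.normal(10.0, 2.0, half), rng.normal(24.0, 2.0, n - half)])
    label = np.concatenate([np.ones(half, dtype=int), np.zeros(n - half, dtype=int)])
    return pd.DataFrame(
        {
            "SST": rng.normal(15.0, 3.0, n),
            "SBT": sbt + rng.normal(0.0, noise, n),
            "SSS": rng.normal(32.0, 1.0, n),
            "SBS": rng.normal(33.0, 1.0, n),
            "label": label,
        }
    )


@pytest.fixture()
def separable_table():
    return make_separable_table()


def random_stack(seed: int = 0, grid: GridSpec = SMALL_GRID) -> PredictorStack:
    rng = np.random.default_rng(seed)
    shape = grid.shape
    v = {
        "SST": rng.uniform(5, 25, shape),
        "SBT": rng.uniform(2, 20, shape),
        "SSS": rng.uniform(28, 35, shape),
        "SBS": rng.uniform(30, 35, shape),
    }
    mask = rng.random(shape) < 0.1
    for arr in v.values():
        arr[mask] = np.nan
    return PredictorStack(spec=grid, variables=v)
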