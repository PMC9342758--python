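"""Shared fixtures: small deterministic landscapes, stacks, and tables."""

from __future__ import annotations

import numpy as np
import pytest

from habsel.covariates import EvennessParams, build_stack
from habsel.landscape_sim import (
    HabitatClassMap,
    LandscapeConfig,
    generate_landscape,
    generate_roads,
)


@pytest.fixture(scope="session")
def small_config() -> LandscapeConfig:
    return LandscapeConfig(
        n_rows=120, n_cols=120, cell_size=30.0, smoothing_length=200.0, seed=42
    )


@pytest.fixture(scope="session")
def small_map(small_config) -> HabitatClassMap:
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_roads(small_config):
    return generate_roads(small_config, seed=7)


@pytest.fixture(scope="session")
def small_stack(small_map, small_roads):
    return build_stack(small_map, small_roads, EvennessParams(window_radius=300.0))


@pytest.fixture(scope="session")
def random_map_30() -> HabitatClassMap:
    """Unstructured 30x30 map with all five classes present."""
    rng = np.random.default_rng(123)
    classes = rng.integers(0, 5, size=(30, 30)).astype(np.int8)
    for k in range(5):  # guarantee presence of every class
        classes[k, k] = k
    return HabitatClassMap(classes=classes, cell_size=30.0)
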