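"""Shared fixtures: small synthetic scenes generated at test time."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from temporalcropnet import (
    FieldConfig,
    PointCloud,
    generate_field_series,
    generate_growth_dataset,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def grid_cloud():
    """10x10 unit grid at z=0 (homogeneous neighbourhoods)."""
    x, y = np.meshgrid(np.arange(10.0), np.arange(10.0))
    xyz = np.stack([x.ravel(), y.ravel(), np.zeros(100)], axis=1)
    return PointCloud(xyz)


@pytest.fixture(scope="session")
def small_field():
    """A 3x3-plant field series with truth, small enough for fast tests."""
    cfg = FieldConfig(
        n_rows=3,
        n_cols=3,
        margin=1.0,
        h_inf_range=(0.5, 0.9),
        points_per_plant=1500,
        seed=21,
    )
    clouds, truth = generate_field_series(cfg)
    return cfg, clouds, truth


@pytest.fixture(scope="session")
def growth_series():
    return generate_growth_dataset(60, noise_sd=0.05, seed=5)
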