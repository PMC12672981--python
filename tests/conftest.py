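import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from forestuse.synthetic import (
    DemarcationParams,
    LandscapeConfig,
    UrbanParams,
    WaterParams,
    generate_landscape,
)


def tiny_config(**overrides) -> LandscapeConfig:
    """A small, fast study region used across the suite."""
    base = dict(
        extent=(0.0, 0.0, 40_000.0, 40_000.0),
        pixel_size=500.0,
        n_counties=2,
        n_communities=10,
        n_urban_communities=2,
        demarcation=DemarcationParams(total_km_t0=30.0, total_km_t1=80.0),
        water=WaterParams(n_rivers=2, n_reservoirs=2),
        urban=UrbanParams(n_polygons=2),
        seed=11,
    )
    base.update(overrides)
    return LandscapeConfig(**base)


@pytest.fixture(scope="session")
def tiny_landscape():
    return generate_landscape(tiny_config())


def point_df(points, prefix="c", county="county01") -> pd.DataFrame:
    """Settlement-style DataFrame from raw (x, y) tuples."""
    return pd.DataFrame(
        {
            "id": [f"{prefix}{i:03d}" for i in range(len(points))],
            "county": county,
            "ethnic_group": None,
            "source": f"list_{prefix}",
            "geometry": [Point(x, y) for x, y in points],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
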