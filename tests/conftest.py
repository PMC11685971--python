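import numpy as np
import pandas as pd
import pytest

from satdisp.config import Scenario, WorldConfig
from satdisp.synthetic_world import generate_world


def tiny_config(seed: int = 7, **overrides) -> WorldConfig:
    """A fast two-city world: one baseline and one war-year month."""
    base = dict(
        n_cities=2,
        aoi_size_km=2.0,
        aoi_origin_offset_m=0.0,
        city_populations=(12_000.0, 9_000.0),
        months={2019: [5], 2022: [5]},
        scenario=Scenario(multipliers={2022: {"city_0": 1.5, "city_1": 0.5}}),
        seed=seed,
    )
    base.update(overrides)
    return WorldConfig(**base)


@pytest.fixture(scope="session")
def default_world():
    """The bundled four-city study world (default configuration)."""
    return generate_world(WorldConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_world():
    return generate_world(tiny_config())
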