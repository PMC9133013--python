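import numpy as np
import pandas as pd
import pytest

from nrloss import (
    SimulationConfig,
    compute_efs,
    generate_county_survey,
    generate_grid,
    generate_observations,
)


@pytest.fixture(scope="session")
def desk_config() -> SimulationConfig:
    """Small study: reduced corpus, 60 counties, 20x20 grid."""
    return SimulationConfig(
        n_per_pathway={"NO": 40, "N2O": 80, "NH3": 50, "NO3_leaching": 50, "runoff": 30},
        n_counties=60,
        nx=20,
        ny=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def corpus(desk_config) -> pd.DataFrame:
    return generate_observations(desk_config)


@pytest.fixture(scope="session")
def ef_records(corpus) -> pd.DataFrame:
    return compute_efs(corpus)


@pytest.fixture(scope="session")
def survey(desk_config) -> pd.DataFrame:
    return generate_county_survey(desk_config)


@pytest.fixture(scope="session")
def grid_stack(desk_config):
    return generate_grid(desk_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
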