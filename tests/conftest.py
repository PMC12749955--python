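import numpy as np
import pytest

from sdproxy import (
    EnsembleConfig,
    SyntheticConfig,
    build_sdp_table,
    generate_covariate_grids,
    generate_survey,
    train_ensemble,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(
        grid_rows=16,
        grid_cols=16,
        years=tuple(range(2013, 2020)),
        survey_years=(2015, 2018),
        n_points_per_year=80,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_stack(small_cfg):
    return generate_covariate_grids(small_cfg)


@pytest.fixture(scope="session")
def small_survey(small_cfg, small_stack):
    return generate_survey(small_stack, small_cfg)


@pytest.fixture(scope="session")
def small_sdp_table(small_survey):
    return build_sdp_table(small_survey)


@pytest.fixture(scope="session")
def tiny_ensemble(small_sdp_table):
    return train_ensemble(small_sdp_table, EnsembleConfig(n_models=3, n_trees=25, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
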