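"""Shared fixtures: a scaled-down synthetic cohort reused across tests.

The small cohort keeps the full three-arm design (19 mice, 41 bins, two
regions) but fewer analytes so that preprocessing and the mixed-model
machinery stay fast; the generator itself is identical to the full-size one.
"""

import numpy as np
import pytest

import dialmet as dm


@pytest.fixture(scope="session")
def design():
    return dm.default_design()


@pytest.fixture(scope="session")
def small_params():
    return dm.GeneratorParams(
        seed=7,
        n_known_analytes=8,
        n_state_dependent=3,
        n_depletion=1,
        n_negative_coupled=1,
        n_planted_outliers=5,
        n_unknown_features=5,
        n_unknown_state_dependent=2,
    )


@pytest.fixture(scope="session")
def cohort(small_params):
    return dm.simulate_cohort(small_params)


@pytest.fixture(scope="session")
def zmatrix(cohort, design):
    table, wake, band, truth = cohort
    return dm.preprocess(table, wake, design)


@pytest.fixture(scope="session")
def null_cohort(design):
    """Cohort with all state slopes zero: no condition effect anywhere."""
    params = dm.GeneratorParams(
        seed=19,
        n_known_analytes=8,
        n_state_dependent=0,
        n_depletion=0,
        n_negative_coupled=0,
        wake_slope=0.0,
        sleep_slope=0.0,
    )
    return dm.simulate_cohort(params)


@pytest.fixture(scope="session")
def null_zmatrix(null_cohort, design):
    table, wake, band, truth = null_cohort
    return dm.preprocess(table, wake, design)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
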