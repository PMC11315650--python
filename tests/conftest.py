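import dataclasses

import numpy as np
import pytest

from slcma import SimulationParams, apply_missingness, simulate_cohort, simulate_offences


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams(n_participants=4000, seed=11)


@pytest.fixture(scope="session")
def cohort(default_params):
    """Complete synthetic cohort under the default (sensitive-period) mechanism."""
    return simulate_cohort(default_params)


@pytest.fixture(scope="session")
def cohort_missing(default_params, cohort):
    return apply_missingness(cohort, default_params)


@pytest.fixture(scope="session")
def offences(default_params, cohort):
    return simulate_offences(cohort, default_params)


@pytest.fixture(scope="session")
def null_params():
    return SimulationParams.for_mechanism("null", n_participants=4000, seed=23)


def replace(params, **kw):
    return dataclasses.replace(params, **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
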