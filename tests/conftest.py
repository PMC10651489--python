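import numpy as np
import pytest

from needscape import (
    DEFAULT_GEOMETRY,
    PARAMS_FIT_ALL_SESSIONS,
    DatasetSpec,
    generate_dataset,
)
from needscape.behavior_stats import behavioral_needs


@pytest.fixture(scope="session")
def geom():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def fitted_params():
    return PARAMS_FIT_ALL_SESSIONS


@pytest.fixture(scope="session")
def assay_dataset(geom, fitted_params):
    """22 two-hour sessions at the fitted parameters with experiment-like
    initial needs — the standard simulated assay pool."""
    spec = DatasetSpec(n_sessions=22, seed=101)
    sessions, ground_truth = generate_dataset(spec, geom, fitted_params)
    return sessions, ground_truth


@pytest.fixture(scope="session")
def assay_annotated(assay_dataset):
    sessions, _ = assay_dataset
    return behavioral_needs(sessions)


@pytest.fixture(scope="session")
def small_dataset(geom, fitted_params):
    """A light 4-session pool for unit tests that only need plumbing."""
    spec = DatasetSpec(n_sessions=4, seed=7)
    return generate_dataset(spec, geom, fitted_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
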