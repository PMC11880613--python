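"""Shared fixtures: small seeded phantoms and preprocessed cohorts.

Everything is generated programmatically at test time; the session
scope keeps the cost of phantom generation and preprocessing to one
pass for the whole suite.
"""

import numpy as np
import pytest

from xaimri.phantom import PhantomSpec, generate_cohort, generate_subject
from xaimri.preprocess import PreprocessConfig, preprocess_subject

SMALL_GRID = (48, 48, 40)
CUBE = 32


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(grid_shape=SMALL_GRID, seed=7)


@pytest.fixture(scope="session")
def small_subject(small_spec):
    return generate_subject(small_spec, "phantom-000")


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec, 4)


@pytest.fixture(scope="session")
def preprocessed_cohort(small_cohort):
    cfg = PreprocessConfig.scaled(SMALL_GRID, CUBE)
    return [preprocess_subject(s, cfg) for s in small_cohort]


@pytest.fixture(scope="session")
def preprocessed_subject(preprocessed_cohort):
    return preprocessed_cohort[0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
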