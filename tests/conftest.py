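import warnings

import numpy as np
import pytest

from thermocad.features import feature_table
from thermocad.phantoms import generate_dataset

# the benchmark cohort used by the end-to-end and class-direction tests;
# session-scoped because feature extraction over 200 images dominates runtime
COHORT_SEED = 7
N_PER_CLASS = 100


@pytest.fixture(scope="session")
def phantom_cohort():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        images, labels, specs = generate_dataset(N_PER_CLASS, seed=COHORT_SEED)
    return images, labels, specs


@pytest.fixture(scope="session")
def phantom_table(phantom_cohort):
    images, labels, _ = phantom_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = feature_table(images)
    return table, labels.loc[table.index]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
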