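import numpy as np
import pytest

from embryoarrest.datamodel import AnalysisConfig
from embryoarrest.pipeline import normalize_chain
from embryoarrest.simulate import GeneratorParams, simulate_dataset

# Reduced problem size for fast unit tests; the acceptance suite runs the
# default (study-condition) generator instead.
SMALL = dict(
    n_genes=800,
    n_te_features=60,
    embryos_per_stage=4,
    n_arrested=(4, 3, 3),
    n_treated=2,
    mean_depth=2e5,
    n_aneuploid=2,
    seed=11,
)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(GeneratorParams(**SMALL))


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(GeneratorParams(seed=5))


@pytest.fixture(scope="session")
def default_layers(default_dataset):
    m, ann, st, truth = default_dataset
    return normalize_chain(m, ann, AnalysisConfig())


@pytest.fixture(scope="session")
def small_layers(small_dataset):
    m, ann, st, truth = small_dataset
    return normalize_chain(m, ann, AnalysisConfig())
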