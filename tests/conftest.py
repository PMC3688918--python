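import numpy as np
import pytest

from hypoxmet.preprocessing import preprocess
from hypoxmet.synthetic import GeneratorConfig, generate, paper_shape_fixture

#: reduced design used where full 365-feature tables are unnecessary
SMALL_DESIGN = dict(
    n_features=60, n_blank_features=20, n_lowfreq_features=20, n_discriminant=4
)


def small_config(**overrides) -> GeneratorConfig:
    kw = dict(SMALL_DESIGN)
    kw.update(overrides)
    return GeneratorConfig(**kw)


def null_config(**overrides) -> GeneratorConfig:
    """Exchangeable-label configuration: no planted effect, no class shift
    of the latent response score."""
    return small_config(n_discriminant=0, response_class_shift=0.0, **overrides)


@pytest.fixture(scope="session")
def paper_dataset():
    return paper_shape_fixture(seed=17)


@pytest.fixture(scope="session")
def preprocessed(paper_dataset):
    table, truth = paper_dataset
    return preprocess(table), truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
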