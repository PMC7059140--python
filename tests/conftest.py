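import numpy as np
import pandas as pd
import pytest

from kcml.annotations import CatalogEntry
from kcml.core import TrainConfig, train_term_classifier
from kcml.profiles import feature_columns
from kcml.synthetic import ScreenSpec, TermSpec, generate_screen

PLANTED_SEED = 11


@pytest.fixture(scope="session")
def planted_screen():
    """Default planted-signal fixture: 2,000 genes x 200 features, one term
    of 150 genes with 10 informative features shifted by 1.0 SD."""
    spec = ScreenSpec(
        n_genes=2000,
        n_features=200,
        missing_rate=0.0,
        terms=(TermSpec("T000", n_positive=150, n_informative=10, effect_size=1.0),),
    )
    return generate_screen(spec, seed=PLANTED_SEED)


@pytest.fixture(scope="session")
def planted_matrix(planted_screen):
    m, _, _ = planted_screen
    return m[feature_columns(m)]


@pytest.fixture(scope="session")
def planted_classifier(planted_screen, planted_matrix):
    _, _, truth = planted_screen
    entry = CatalogEntry("T000", frozenset(truth.positives["T000"]))
    return train_term_classifier(entry, planted_matrix, cfg=TrainConfig(rng_seed=PLANTED_SEED))


@pytest.fixture(scope="session")
def small_screen():
    """Cheap strongly separated screen for fast end-to-end training tests."""
    spec = ScreenSpec(
        n_genes=300,
        n_features=30,
        missing_rate=0.0,
        terms=(TermSpec("S000", n_positive=60, n_informative=6, effect_size=1.5),),
    )
    return generate_screen(spec, seed=5)


@pytest.fixture(scope="session")
def small_classifier(small_screen):
    m, _, truth = small_screen
    entry = CatalogEntry("S000", frozenset(truth.positives["S000"]))
    return train_term_classifier(
        entry, m[feature_columns(m)], cfg=TrainConfig(rng_seed=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
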