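import numpy as np
import pytest

from dcgat.evaluation import SplitSpec, make_split, train_model
from dcgat.synthetic import fixture_small


@pytest.fixture(scope="session")
def fixture_data():
    """The frozen small synthetic instance (40 proteins, 60 drugs, 4 clusters)."""
    return fixture_small()


@pytest.fixture(scope="session")
def warm_split(fixture_data):
    pe, de, table, _ = fixture_data
    spec = SplitSpec(strategy="warm", seed=0, negative_ratio=1)
    return make_split(table, de.ids, pe.ids, spec)


@pytest.fixture(scope="session")
def trained_model(fixture_data, warm_split):
    """Full model trained on the fixture's warm split (shared across tests)."""
    pe, de, _, _ = fixture_data
    train_t, val_t, _ = warm_split
    return train_model(
        pe, de, train_t, val_t, max_epochs=100, patience=20, random_state=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
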