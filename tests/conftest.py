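import numpy as np
import pytest

import dcanet
from dcanet import CVConfig, DCAModel, DCANetwork
from dcanet.synthetic import SyntheticSpec, generate_property_table


@pytest.fixture(scope="session")
def property_table():
    """Random low-rank 20 x 30 property table."""
    return generate_property_table(SyntheticSpec(n_properties=30, seed=7))


@pytest.fixture(scope="session")
def embedding(property_table):
    return dcanet.fit_embedding(property_table)


@pytest.fixture
def toy_network():
    """d1-c1, d1-c2, d2-c2, d2-c3."""
    A = np.array([[1, 1, 0], [0, 1, 1]], dtype=np.int8)
    return DCANetwork.from_adjacency(A, drugs=("d1", "d2"), clusters=("c1", "c2", "c3"))


@pytest.fixture(scope="session")
def fitted_preset():
    """Fitted model on the planted-signal synthetic preset at defaults."""
    model = DCAModel.from_synthetic(SyntheticSpec(seed=0))
    return model.fit()


@pytest.fixture(scope="session")
def preset_benchmark_report(fitted_preset):
    """CN cross-validation with the 100-repetition chance baseline."""
    return fitted_preset.evaluate("CN", CVConfig(seed=0, repetitions=100), benchmark=True)
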