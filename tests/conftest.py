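import numpy as np
import pytest

from autoscore_irt import (
    Item2PL,
    QuadratureGrid,
    SimulationCondition,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid():
    return QuadratureGrid.from_normal_prior(n_nodes=100, lower=-6.0, upper=6.0)


@pytest.fixture
def unit_item():
    return Item2PL(a=1.0, b=0.0)


@pytest.fixture(scope="session")
def small_cer_dataset():
    """A 200-person, 8-item constant-error-rate dataset."""
    cond = SimulationCondition(n_items=8, n_persons=200, error_balance="balanced")
    return generate_dataset(cond, seed=777)


@pytest.fixture(scope="session")
def small_ver_dataset():
    cond = SimulationCondition(
        n_items=8, n_persons=200, error_balance="balanced", model_kind="VER"
    )
    return generate_dataset(cond, seed=778)
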