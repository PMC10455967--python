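import numpy as np
import pytest

from petrokin import (
    ElementCounts,
    SequentialExchangeModel,
    SimulationConfig,
    parse_formula,
)


@pytest.fixture(scope="session")
def petrosamine_cation() -> ElementCounts:
    """The C21H17BrN3O2 molecular cation studied throughout."""
    return parse_formula("C21H17BrN3O2").with_charge(+1)


@pytest.fixture(scope="session")
def reference_model() -> SequentialExchangeModel:
    """Fitted exchange rates of the reference experiment (s^-1)."""
    return SequentialExchangeModel(k1=0.1311, k2=0.0755)


@pytest.fixture()
def noiseless_config(reference_model) -> SimulationConfig:
    return SimulationConfig(model=reference_model, noise_cv=0.0, seed=0)


@pytest.fixture()
def noisy_config(reference_model) -> SimulationConfig:
    """The reference experiment's conditions: triplicate, 15 s grid, 3% noise."""
    return SimulationConfig(model=reference_model, noise_cv=0.03, seed=20230811)
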