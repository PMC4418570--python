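import numpy as np
import pytest

from daniopond.deb import DEBParams, compound_parameters
from daniopond.food import FoodParams
from daniopond.ibm import IBMParams, run_ibm


@pytest.fixture(scope="session")
def deb() -> DEBParams:
    return DEBParams()


@pytest.fixture(scope="session")
def comp(deb):
    return compound_parameters(deb)


@pytest.fixture(scope="session")
def ibm_params() -> IBMParams:
    return IBMParams()


@pytest.fixture(scope="session")
def food_params() -> FoodParams:
    return FoodParams()


@pytest.fixture(scope="session")
def short_run():
    """A 120-day default-configuration run shared across invariant tests."""
    return run_ibm(n_days=120, seed=42)
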