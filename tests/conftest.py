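import numpy as np
import pytest

from autozyg.pedigree import Individual, Pedigree
from autozyg.sim import (
    SimConfig,
    consanguineous_study_pedigree,
    default_design,
    first_cousin_pedigree,
    simulate_study,
)


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        [
            Individual("F", sex="male", affected=False),
            Individual("M", sex="female", affected=False),
            Individual("K", "F", "M", affected=True),
        ]
    )


@pytest.fixture
def cousin_ped() -> Pedigree:
    return first_cousin_pedigree()


@pytest.fixture
def study_ped() -> Pedigree:
    return consanguineous_study_pedigree()


@pytest.fixture(scope="session")
def study():
    """One complete simulated study, shared across read-only tests."""
    return simulate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
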