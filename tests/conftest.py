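import numpy as np
import pytest

from synkin import (
    AssayConditions,
    KineticParameters,
    ObservationParameters,
    PhaseState,
    get_fixture,
)


@pytest.fixture
def wt():
    return get_fixture("WT")


@pytest.fixture
def wt_conditions():
    return AssayConditions(monomer_conc=50.0, seed_conc=2.5)


@pytest.fixture
def wt_params():
    return KineticParameters(k_plus=2087.0, m_eq=10.5)


@pytest.fixture
def unit_obs():
    return ObservationParameters(beta_A=1.0, beta_B=1.0)


@pytest.fixture
def wt_state(wt):
    return wt.initial_state()


def make_state(m, M_A, M_B, mean_length_nm, rho=2.0 / 0.47):
    return PhaseState(m=m, M_A=M_A, M_B=M_B,
                      P_uM=(M_A + M_B) / (mean_length_nm * rho))
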