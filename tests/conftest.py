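import numpy as np
import pytest

from ssimod.io_cli import fixture
from ssimod.model_build import build_rate_model
from ssimod.multieq import find_equilibria

# reference values of the worked bistable example (5-decimal precision);
# coordinates are (C_1, C_2, C_3) in the state order (B, C, D)
EQ_LOW_C2 = (0.35000, 0.72835, 2.44647)
EQ_HIGH_C2 = (0.35438, 2.48512, 0.78621)
EQ_MID_C2 = (0.34243, 1.11200, 1.34743)

# reference Jacobian spectra: the all-negative spectrum belongs to the
# (stable) median-C_2 equilibrium, the one-positive spectrum to the
# (unstable) smallest-C_2 equilibrium
SPECTRUM_STABLE = (-9.1666, -0.1730, -0.0267)
SPECTRUM_UNSTABLE = (-8.8773, -0.3005, 0.0209)


@pytest.fixture(scope="session")
def fig4():
    return fixture("fig4")


@pytest.fixture(scope="session")
def fig4_model(fig4):
    module, params = fig4
    return build_rate_model(module, params)


@pytest.fixture(scope="session")
def fig4_equilibria(fig4_model):
    """The three equilibria, sorted by C_2 ascending."""
    records = find_equilibria(fig4_model, seed=1)
    assert len(records) == 3
    return records


@pytest.fixture(scope="session")
def chain_model():
    module, params = fixture("chain_ssn")
    return build_rate_model(module, params)


def finite_difference_jacobian(model, c, rel_h=1e-7):
    c = np.asarray(c, dtype=float)
    n = model.n_states
    jac = np.zeros((n, n))
    for k in range(n):
        h = rel_h * max(1.0, abs(c[k]))
        e = np.zeros(n)
        e[k] = h
        jac[:, k] = (model.rhs(c + e) - model.rhs(c - e)) / (2 * h)
    return jac
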