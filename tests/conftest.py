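import numpy as np
import pytest

from lvcdyn.fixtures import FixtureSpec, generate_fixture
from lvcdyn.model import BasisSpec, LVCModel, ModeSet


def random_lvc(n_states=3, n_modes=4, seed=0, soc=0.0, complex_eta=False):
    """Dense random LVC model for property tests (not via generate_fixture,
    so every coupling entry is populated)."""
    rng = np.random.default_rng(seed)
    modes = ModeSet(frequencies=rng.uniform(0.001, 0.01, size=n_modes))
    basis = BasisSpec.singlets(n_states)
    E = np.sort(rng.uniform(0.0, 0.2, size=n_states))
    kappa = rng.normal(0.0, 0.005, size=(n_states, n_modes))
    lam = rng.normal(0.0, 0.002, size=(n_states, n_states, n_modes))
    lam = 0.5 * (lam + np.swapaxes(lam, 0, 1))
    for i in range(n_states):
        lam[i, i] = 0.0
    eta = np.zeros((n_states, n_states), dtype=complex)
    if soc > 0:
        eta = rng.normal(0, soc, (n_states, n_states))
        if complex_eta:
            eta = eta + 1j * rng.normal(0, soc, (n_states, n_states))
        eta = eta + eta.conj().T
        np.fill_diagonal(eta, 0.0)
    return LVCModel(modes=modes, basis=basis, E=E, eta=eta, kappa=kappa, lam=lam)


@pytest.fixture
def three_state_model():
    return random_lvc(3, 4, seed=11)


@pytest.fixture
def soc_model():
    return generate_fixture(FixtureSpec(
        n_modes=2, multiplets=(("S", 0.0, 2), ("T", 1.0, 1)),
        soc_scale_cm1=150.0, seed=5))
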