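import numpy as np
import pytest
from hypothesis import settings

from cuproflux import build_canonical_network, stoichiometric_matrix
from cuproflux.dynamics import anneal
from cuproflux.pathways import nonnegative_pathway_basis, null_basis
from cuproflux.pipeline import run_calibration
from cuproflux.templates import default_template

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def network():
    return build_canonical_network()


@pytest.fixture(scope="session")
def S(network):
    return stoichiometric_matrix(network)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def pathway_basis(S):
    return nonnegative_pathway_basis(null_basis(S))


@pytest.fixture(scope="session")
def calibration():
    """Full steady-state calibration on the default titration template."""
    return run_calibration(seed=0)


@pytest.fixture(scope="session")
def annealed_states(calibration):
    """Attracting steady state for each titration condition."""
    out = {}
    for p in calibration.profiles:
        out[p.label] = anneal(calibration.system(p.copper), p.concentrations)
    return out


@pytest.fixture(scope="session")
def baseline14(calibration):
    """Annealed state of the reference cell at COPPER = 14 μM."""
    res = anneal(calibration.system(14.0), calibration.profile("M10").concentrations)
    assert res.converged
    return res.concentrations


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
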