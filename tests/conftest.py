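import numpy as np
import pytest

from quenchsim import model_core as mc, stability as st


@pytest.fixture(scope="session")
def toy_params():
    model, p = mc.load_params("toy_fig2")
    return p


@pytest.fixture(scope="session")
def set1_params():
    _m, p = mc.load_params("set1")
    return p


@pytest.fixture(scope="session")
def set2_params():
    _m, p = mc.load_params("set2")
    return p


@pytest.fixture(scope="session")
def toy_ss(toy_params):
    return mc.find_steady_state("toy", toy_params)


@pytest.fixture(scope="session")
def set1_ss(set1_params):
    return mc.find_steady_state("full", set1_params)


@pytest.fixture(scope="session")
def set2_ss(set2_params):
    return mc.find_steady_state("full", set2_params)


@pytest.fixture(scope="session")
def toy_lin(toy_params, toy_ss):
    return st.linearize("toy", toy_params, toy_ss)


@pytest.fixture(scope="session")
def set2_lin(set2_params, set2_ss):
    return st.linearize("full", set2_params, set2_ss)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120126)
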