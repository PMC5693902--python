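import numpy as np
import pytest

from landscaper import (DynamicalSystem, HillEdge, HillNetworkSpec,
                        make_fixture)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def double_well_1d():
    return make_fixture("double_well_1d")


@pytest.fixture
def rotational_ou():
    return make_fixture("rotational_ou", q=1.0)


@pytest.fixture
def gradient_plus_curl():
    return make_fixture("gradient_plus_curl", q=1.0)


@pytest.fixture
def variable_curl():
    return make_fixture("variable_curl", q0=1.0, c=1.0)


@pytest.fixture
def toggle_switch_spec():
    """Two-gene mutual-inhibition network: a classic bistable switch."""
    return HillNetworkSpec(
        nodes=["a", "b"],
        edges=[
            HillEdge(source="b", target="a", sign="inhibition", a=2.0, n=4.0, k=1.0),
            HillEdge(source="a", target="b", sign="inhibition", a=2.0, n=4.0, k=1.0),
        ],
        degradation={"a": 1.0, "b": 1.0},
        basal={"a": 0.1, "b": 0.1},
    )


@pytest.fixture
def multiplicative_system():
    """1-D system with state-dependent diffusion for gradient/action tests."""
    def f(x):
        x = np.asarray(x, dtype=float)
        return -x

    def D(x):
        return np.array([[1.0 + 0.5 * x[0] ** 2]])

    return DynamicalSystem(N=1, f=f, jac=lambda x: np.array([[-1.0]]),
                           D=D, vectorized=True, name="multiplicative_ou")
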