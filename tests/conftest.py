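import numpy as np
import pytest

import stochshield as ss


@pytest.fixture(scope="session")
def unit_chain():
    """3-state chain with all rates 1 and the end state observable."""
    return ss.three_state_chain(1.0, 1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def example_a_chain():
    return ss.example_a()


@pytest.fixture(scope="session")
def example_b_chain():
    return ss.example_b()


@pytest.fixture(scope="session")
def nachr_low():
    """nAChR at the low (bursty) agonist concentration 0.5 uM."""
    return ss.nachr_model(0.5)


@pytest.fixture(scope="session")
def nachr_high():
    return ss.nachr_model(100.0)


@pytest.fixture(
    scope="session",
    params=["unit", "example-A", "example-B", "nachr-0.5", "nachr-100", "random"],
)
def reversible_model(request):
    """A small bank of reversible fixture models for shared property tests."""
    name = request.param
    if name == "unit":
        return ss.three_state_chain(1, 1, 1, 1)
    if name == "example-A":
        return ss.example_a()
    if name == "example-B":
        return ss.example_b()
    if name == "nachr-0.5":
        return ss.nachr_model(0.5)
    if name == "nachr-100":
        return ss.nachr_model(100.0)
    # a random reversible 4-state chain (chains satisfy detailed balance)
    rng = np.random.default_rng(20240613)
    r = rng.lognormal(0.0, 1.0, size=6)
    return ss.build_model(
        states=("1", "2", "3", "4"),
        edges=[(1, 2, r[0]), (2, 1, r[1]), (2, 3, r[2]),
               (3, 2, r[3]), (3, 4, r[4]), (4, 3, r[5])],
        measurement=[0.0, 0.0, 1.0, 1.0],
    )
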