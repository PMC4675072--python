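import numpy as np
import pytest

from condchain import ChainSpec, make_atb_chain, make_drunkard_walk


@pytest.fixture(scope="session")
def drunkard():
    """The 17-state symmetric walk: home at 0, bar at 16, fair steps."""
    return make_drunkard_walk(15, 0.5)


@pytest.fixture(scope="session")
def ctmc4():
    """Hand-solvable 4-state CTMC: transients {1,2}, absorbers {g,p}.

    Rates 1->2: 1, 1->g: 1, 2->1: 1, 2->p: 2.  Absorption-at-p
    probabilities solve to pi_1 = 0.4, pi_2 = 0.8 by a 2x2 system.
    """
    kern = np.zeros((4, 4))
    labels = ("1", "2", "g", "p")
    kern[0, 1] = 1.0
    kern[0, 2] = 1.0
    kern[1, 0] = 1.0
    kern[1, 3] = 2.0
    return ChainSpec(labels, "continuous", kern, frozenset({"g", "p"}))


@pytest.fixture(scope="session")
def atb():
    """Reversible A<->T<->B chain with w_TA = 2, w_TB = 1."""
    return make_atb_chain({"w_at": 1.0, "w_ta": 2.0, "w_tb": 1.0, "w_bt": 1.0})
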