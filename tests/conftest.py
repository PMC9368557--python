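import numpy as np
import pytest

from pocketdyn.synthetic import gen_state_switching_trajectory, gen_toy_complex


@pytest.fixture(scope="session")
def toy():
    return gen_toy_complex(1)


@pytest.fixture(scope="session")
def three_state(toy):
    """100/60/40-frame three-state trajectory with its planted schedule."""
    schedule = ["state0"] * 100 + ["state1"] * 60 + ["state2"] * 40
    traj = gen_state_switching_trajectory(toy, schedule, seed=11)
    return schedule, traj


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
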