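import numpy as np
import pytest

import stochmle as sm


@pytest.fixture
def pure_birth():
    return sm.builtin_model("pure_birth")


@pytest.fixture
def birth_death():
    return sm.builtin_model("birth_death")


@pytest.fixture
def decay_dimer():
    return sm.builtin_model("decay_dimer_reversible")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_birth_death_toy():
    """Hand-checkable birth-death trajectory: x0=2, death after 1, birth
    after 2 more, quiet until T=4.  r=(1,1), H_birth=4, H_death=6."""
    bm = sm.builtin_model("birth_death")
    traj = sm.CompleteTrajectory(
        x0=np.array([2]),
        waiting_times=np.array([1.0, 2.0]),
        reaction_indices=np.array([1, 0]),  # death then birth
        terminal_residual=1.0,
        horizon=4.0,
    )
    return bm.network, traj


@pytest.fixture
def birth_death_toy():
    return make_birth_death_toy()


def random_toy_trajectory(rng, network, theta_scale=1.0, horizon=5.0):
    """Simulate a small trajectory with random rates for oracle tests."""
    m = network.n_reactions
    theta = theta_scale * rng.uniform(0.2, 2.0, size=m)
    x0 = rng.integers(1, 20, size=network.n_species)
    return theta, sm.simulate_trajectory(
        network, theta, x0, sm.SimulationConfig(horizon, max_events=100_000), rng
    )
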