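import numpy as np
import pytest

from clutterlab.environment import environment_pair
from clutterlab.trajectory import Trajectory


@pytest.fixture(scope="session")
def env_pair():
    return environment_pair(seed=3)


@pytest.fixture(scope="session")
def env1(env_pair):
    return env_pair[0]


@pytest.fixture(scope="session")
def env2(env_pair):
    return env_pair[1]


def make_traj(x, y=None, z=None, t=None, bee_id="bee01", trial=5, env_id="env1", fs=100.0):
    """Build a trajectory from coordinate arrays, defaulting y/z/t sensibly."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if y is None:
        y = np.zeros(n)
    if z is None:
        z = np.full(n, 150.0)
    if t is None:
        t = np.arange(n) / fs
    return Trajectory(bee_id=bee_id, trial=trial, environment_id=env_id,
                      t=np.asarray(t, float), x=x, y=np.asarray(y, float),
                      z=np.asarray(z, float))


@pytest.fixture
def straight_traj():
    """A perfectly direct flight spanning the full tunnel at 0.4 m/s."""
    n = 501
    return make_traj(np.linspace(0.0, 2000.0, n))
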