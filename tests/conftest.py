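import logging

import pytest

from trajkit import Environment, Trajectory, cartesian_product
from trajkit.models import multiply


@pytest.fixture()
def traj():
    return Trajectory("testtraj")


@pytest.fixture()
def multiply_env(tmp_path):
    """Environment wired to the two-parameter product model, 12 points."""
    env = Environment("multiply", filename=str(tmp_path / "multiply.h5"),
                      log_level=logging.ERROR)
    env.traj.add_parameter("x", 1.0, comment="first dimension")
    env.traj.add_parameter("y", 1.0, comment="second dimension")
    env.traj.explore(cartesian_product(
        {"x": [1.0, 2.0, 3.0, 4.0], "y": [6.0, 7.0, 8.0]}))
    yield env
    env.close()


@pytest.fixture()
def multiply_outcomes(multiply_env):
    return multiply_env.run(multiply)
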