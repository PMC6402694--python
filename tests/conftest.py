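import numpy as np
import pandas as pd
import pytest

from delaystate import synthetic


@pytest.fixture(scope="session")
def default_params():
    return synthetic.GeneratorParams()


@pytest.fixture(scope="session")
def ring_layout():
    return synthetic.make_target_layout("ring", "J")


@pytest.fixture(scope="session")
def rings3_layout():
    return synthetic.make_target_layout("rings3", "J")


@pytest.fixture(scope="session")
def small_table(ring_layout, default_params):
    """240-trial ring table with default generator settings."""
    return synthetic.simulate_trials(ring_layout, default_params, 10, seed=42)


@pytest.fixture(scope="session")
def line_tables(default_params):
    """Horizontal + vertical tables pooled (12 distances, both sides)."""
    h = synthetic.make_target_layout("horizontal", "J")
    v = synthetic.make_target_layout("vertical", "J")
    return pd.concat(
        [
            synthetic.simulate_trials(h, default_params, 20, seed=7),
            synthetic.simulate_trials(v, default_params, 20, seed=8),
        ],
        ignore_index=True,
    )


def make_states(x, y, condition_id, task="ring"):
    """Minimal NeuralStates frame for geometry unit tests."""
    n = len(x)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "session_id": "s0",
            "task": task,
            "condition_id": condition_id,
            "target_x": np.zeros(n),
            "target_y": np.zeros(n),
            "max_speed": np.zeros(n),
            "max_speed_x": np.zeros(n),
            "max_speed_y": np.zeros(n),
            "x_neural": np.asarray(x, float),
            "y_neural": np.asarray(y, float),
            "speed_neural": np.zeros(n),
        }
    )
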