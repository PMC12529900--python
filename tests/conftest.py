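import numpy as np
import pytest
from hypothesis import settings

from ntcnmr import (
    classify_trajectory,
    default_duplex_spec,
    population_weights,
    sample_trajectory,
    synthetic_class_table,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def class_table():
    return synthetic_class_table(seed=1)


@pytest.fixture(scope="session")
def small_run(class_table):
    """A small synthetic trajectory with its classification and populations."""
    spec = default_duplex_spec(n_frames=400)
    traj, labels = sample_trajectory(spec, class_table, seed=7)
    assignments = classify_trajectory(traj, class_table)
    weights = population_weights(assignments)
    return {
        "spec": spec,
        "traj": traj,
        "labels": labels,
        "assignments": assignments,
        "weights": weights,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
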