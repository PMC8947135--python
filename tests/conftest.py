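import numpy as np
import pytest

from clutterflight.camera import default_rig
from clutterflight.pipeline import process_experiment
from clutterflight.scene import build_scene
from clutterflight.synthetic import BehaviorConfig, simulate_experiment


@pytest.fixture(scope="session")
def rig():
    return default_rig()


@pytest.fixture(scope="session")
def scene127():
    return build_scene(127)


@pytest.fixture(scope="session")
def small_experiment():
    """A 6-bee seeded experiment with default-noise observations."""
    return simulate_experiment(BehaviorConfig(n_bees=6, seed=42))


@pytest.fixture(scope="session")
def small_run(small_experiment):
    """The small experiment pushed through the full measurement chain."""
    metrics, rejects, records = process_experiment(small_experiment)
    return small_experiment, metrics, rejects, records


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
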