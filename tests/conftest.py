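import numpy as np
import pytest

from dynbody.synthetic import (
    ACTIONS,
    default_skeleton,
    make_impossible,
    simulate_possible_trajectory,
)


@pytest.fixture(scope="session")
def skeleton():
    return default_skeleton()


@pytest.fixture(scope="session")
def small_clip_set(skeleton):
    """16 possible trajectories + mirrored twins, keyed by stimulus id."""
    trajs, labels = {}, {}
    for k in range(16):
        t = simulate_possible_trajectory(
            skeleton, ACTIONS[k % 4], duration_frames=60 + k, seed=100 + k
        )
        trajs[f"pos{k:03d}"] = t
        labels[f"pos{k:03d}"] = "possible"
        trajs[f"imp{k:03d}"] = make_impossible(t)
        labels[f"imp{k:03d}"] = "impossible"
    return trajs, labels


@pytest.fixture
def rng():
    return np.random.default_rng(0)
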