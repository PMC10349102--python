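import numpy as np
import pytest

from nbstates import synthetic as syn


@pytest.fixture(scope="session")
def tiny_gt():
    """Small two-network ground truth shared by fast tests."""
    return syn.generate_ground_truth(
        n_subjects=3,
        n_timepoints=400,
        networks=[("NETA", 6), ("NETB", 8)],
        limbic={"HC": 8, "AM": 5},
        n_episodes=25,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
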