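import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ground_truth():
    from knockoutnet.simfly import make_ground_truth

    return make_ground_truth(4, seed=7)


@pytest.fixture(scope="session")
def short_control_session(small_ground_truth):
    from knockoutnet.simfly import simulate_session

    return simulate_session(small_ground_truth, "control", 30.0, seed=3,
                            render_config=None)
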