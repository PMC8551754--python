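import dataclasses

import numpy as np
import pytest

from tbshape import SimConfig, simulate_trace


@pytest.fixture(scope="session")
def default_trace():
    """30 d, 10 min sampling, mesor 36.4, A 1.0, k 6, noise 0.15."""
    return simulate_trace(SimConfig())


@pytest.fixture(scope="session")
def torpor_trace():
    cfg = dataclasses.replace(
        SimConfig(), torpor_prob_per_day=0.5, torpor_depth_c=8.0, seed=21
    )
    return simulate_trace(cfg)


@pytest.fixture(scope="session")
def burst_trace():
    cfg = dataclasses.replace(
        SimConfig(), burst_rate_per_active_h=0.5, burst_scale_c=1.5, seed=22
    )
    return simulate_trace(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
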