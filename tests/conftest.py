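import numpy as np
import pytest

import avalanche_stats as av


@pytest.fixture(scope="session")
def small_recording():
    """Short emulated 4-channel recording with planted events and spikes."""
    cfg = av.LfpEmulationConfig(n_channels=4, duration=120.0)
    signal, truth, spikes = av.make_lfp_dataset(cfg, seed=20240)
    return cfg, signal, truth, spikes


@pytest.fixture(scope="session")
def pl_sample_continuous():
    return av.make_tail_sample("powerlaw", {"alpha": 2.5, "x_min": 1.0}, 20_000, 7)


@pytest.fixture(scope="session")
def pl_sample_discrete():
    return av.make_tail_sample(
        "powerlaw", {"alpha": 1.5, "x_min": 1.0}, 20_000, 8, mode="discrete"
    )


@pytest.fixture(scope="session")
def exp_sample():
    return av.make_tail_sample("exponential", {"lam": 2.0, "x_min": 1.0}, 20_000, 9)
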