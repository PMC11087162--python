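import pytest

from gatelat import ScenarioConfig, simulate_session

# Small fast scenario shared across module tests: 2 kHz is plenty for
# sub-millisecond checks (one sample = 0.5 ms) and keeps the suite quick.
FAST_FS = 2000.0


@pytest.fixture(scope="session")
def fast_config():
    return ScenarioConfig(
        amplitude=15.0, period=3.0, n_cycles=5, sampling_rate=FAST_FS, seed=11
    )


@pytest.fixture(scope="session")
def noiseless_session(fast_config):
    return simulate_session(fast_config.without_noise())


@pytest.fixture(scope="session")
def noisy_session(fast_config):
    return simulate_session(fast_config)
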