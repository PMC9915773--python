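import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from patchforage import CohortSpec, TaskConfig
from patchforage.mvt import mvt_benchmark

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def benchmarks(config):
    return {d: mvt_benchmark(d, config) for d in config.delays}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
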