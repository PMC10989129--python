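import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from scramblekit import PipelineConfig, build_toy_genome  # noqa: E402


@pytest.fixture(scope="session")
def toy_chrom():
    """~20 kb chromosome with 10 internal loxPsym sites (11 x 1800 bp segments)."""
    return build_toy_genome([1800] * 11, seed=11)


@pytest.fixture(scope="session")
def small_chrom():
    return build_toy_genome([100, 200, 300], seed=1)


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
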