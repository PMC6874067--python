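import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icrotok import GeneratorConfig, featurize, generate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def benchmark_stand_in():
    """Synthetic stand-in for the 378+/500- benchmark (41-mer windows)."""
    return generate(seed=11)


@pytest.fixture(scope="session")
def benchmark_features(benchmark_stand_in):
    X = featurize(benchmark_stand_in.windows)
    return X, benchmark_stand_in.labels


@pytest.fixture(scope="session")
def small_dataset():
    """A small separable dataset for fast pipeline tests."""
    return generate(GeneratorConfig(n_pos=30, n_neg=30, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_window_codes(rng, length=41, pad_left=0, pad_right=0):
    """Random SVV code vector with optional terminal padding."""
    codes = rng.integers(1, 21, size=length)
    codes[length // 2] = 9  # 'K'
    codes[:pad_left] = 0
    if pad_right:
        codes[-pad_right:] = 0
    return codes
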