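import numpy as np
import pytest

from phenotrace import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A fast one-week cohort with coarse GPS sampling and short diaries."""
    return SyntheticConfig(
        n_participants=6,
        weeks=1,
        base_rates={"gps_interval_s": 1800.0},
        audio_params={"duration_s": 4.0, "diaries_per_week": 1.0},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)
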