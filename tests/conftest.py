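import numpy as np
import pytest

from cortifract.synthetic_data import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """Scaled-down cohort for fast unit tests: short sessions, few
    subjects/channels; all other generating parameters at defaults."""
    return CohortConfig(
        n_pd=3, n_control=3, n_channels=4, duration_s=12.0, seed=123
    )
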