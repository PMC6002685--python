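import numpy as np
import pytest

from soaekit.synth import CohortConfig, generate_cohort
from soaekit.types import STFTParams


@pytest.fixture(scope="session")
def small_params():
    """Fast analysis grid for unit tests: 8 kHz, 1 Hz bins."""
    return STFTParams(n_fft=8000, window=4000, hop=1000, sample_rate=8000.0)


@pytest.fixture(scope="session")
def mini_dataset(tmp_path_factory):
    """A tiny on-disk cohort shared by pipeline/CLI/round-trip tests."""
    out = tmp_path_factory.mktemp("cohort") / "ds"
    config = CohortConfig(
        n_mono=2, n_late_bi=1, n_early_bi=1, n_no_soae=1,
        n_trials=6, n_blocks=2, baseline_duration_s=120.0, seed=11,
    )
    generate_cohort(config, out)
    return out, config


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
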