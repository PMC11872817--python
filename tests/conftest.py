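import numpy as np
import pytest

from eegprepost import AnalysisConfig, SyntheticCohortConfig, simulate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def synthetic_recording():
    """A realistic simulated recording (10 s, default cohort settings)."""
    cfg = SyntheticCohortConfig(duration_s=10, seed=7)
    return simulate_subject(cfg, 0, "pre")


@pytest.fixture
def fast_analysis_config():
    """Analysis configuration without the (slow) comodulogram stage."""
    return AnalysisConfig(include_cfc=False)
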