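import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppgcausal import signals, synthetic

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=list(HealthCheck)
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_segment():
    """A preprocessed synthetic segment with exact ABP-derived labels."""
    record, truth = synthetic.gen_ppg(seed=1)
    record.abp = synthetic.gen_abp(120.0, 80.0, hr_bpm=60.0, n_beats=30)
    segment, decision = signals.preprocess_record(record)
    assert segment is not None, decision
    return segment, truth


@pytest.fixture(scope="session")
def small_study():
    """Multi-source SCM study (K=3, n=1000) with ground truth."""
    return synthetic.gen_multisource(seed=0)


@pytest.fixture(scope="session")
def bp_table():
    return synthetic.gen_bp_table(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
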