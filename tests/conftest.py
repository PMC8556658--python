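import numpy as np
import pytest

from sleepgcn.features import ChannelMontage
from sleepgcn.synthetic import SyntheticSpec, cohort_windows, generate_cohort, ring_montage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def montage6() -> ChannelMontage:
    return ring_montage(6)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, fast cohort shared across model-level tests."""
    spec = SyntheticSpec(n_subjects=4, epochs_per_subject=80, n_channels=6, seed=7)
    recordings = generate_cohort(spec)
    return spec, recordings


@pytest.fixture(scope="session")
def tiny_windows(tiny_cohort):
    _, recordings = tiny_cohort
    return cohort_windows(recordings, d=2)
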