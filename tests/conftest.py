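import numpy as np
import pytest

from ndiagree import PCMConfig, ResponseRecord, simulate_frame


@pytest.fixture
def all_zero_record():
    return ResponseRecord("zero", (0,) * 10)


@pytest.fixture
def all_max_record():
    return ResponseRecord("max", (5,) * 10)


@pytest.fixture
def mixed_record():
    return ResponseRecord("mix", (1, 2, 0, 3, 1, 2, 4, 0, 5, 2))


@pytest.fixture
def cohort_frame():
    """Small simulated cohort shared by scoring/agreement/io tests."""
    return simulate_frame(PCMConfig(n_subjects=60, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
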