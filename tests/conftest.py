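import numpy as np
import pytest

from fastdki import build_139_scheme
from fastdki.cohort import scaled_cohort_spec
from fastdki.pipeline import run_cohort


@pytest.fixture(scope="session")
def scheme():
    return build_139_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small noisy cohort (2 patients + 1 control) at the default SNR."""
    return scaled_cohort_spec(seed=7, n_patients=2, n_controls=1)


@pytest.fixture(scope="session")
def noisefree_spec():
    return scaled_cohort_spec(seed=11, n_patients=2, n_controls=1, snr=np.inf)


@pytest.fixture(scope="session")
def noisefree_result(noisefree_spec):
    return run_cohort(noisefree_spec)
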