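import numpy as np
import pytest

from vibrouroflow import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Two sessions per class without background noise (18 s to build)."""
    spec = CohortSpec(class_counts={k: 2 for k in range(6)}, seed=101,
                      noise_snr_db=np.inf)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def reference_cohort():
    """The packaged 76-session reference-distribution cohort."""
    spec = CohortSpec(seed=0)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Three sessions per class at the default 20 dB SNR."""
    spec = CohortSpec(class_counts={k: 3 for k in range(6)}, seed=7)
    return spec, generate_cohort(spec)
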