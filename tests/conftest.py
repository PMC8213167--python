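import numpy as np
import pytest

import autocyto as ac


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Small flagship cohort shared by read-only tests."""
    spec = ac.flagship_cohort(seed=11, events_per_sample=1500, n_samples=5,
                              n_cases=2)
    return spec, ac.generate_cohort(spec)


@pytest.fixture
def simple_filegroup(rng):
    """300-event two-channel sample with an obvious bimodal split on A."""
    a = np.concatenate([rng.normal(-2, 0.4, 150), rng.normal(2, 0.4, 150)])
    b = rng.normal(0, 1, 300)
    em = ac.EventMatrix(np.column_stack([a, b]), ["A", "B"])
    return ac.FileGroup("s1", "subj1", em)
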