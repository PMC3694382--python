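import numpy as np
import pytest

from sasang_shi import synth


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (published study conditions)."""
    return synth.generate_cohort(synth.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_frames(default_cohort):
    return synth.cohort_frames(default_cohort)


@pytest.fixture(scope="session")
def replicate_cohorts():
    """Fifty replicate default cohorts (seeds 1-50), shared across the
    agreement and calibration checks."""
    return [
        synth.generate_cohort(synth.SyntheticConfig(seed=s))
        for s in range(1, 51)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
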