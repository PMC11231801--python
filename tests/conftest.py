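import numpy as np
import pytest

from fcsubtypes.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for plumbing tests: 80 participants, 20 ROIs."""
    return generate_cohort(
        GeneratorConfig(n_participants=80, n_rois=20, seed=7)
    )


@pytest.fixture(scope="session")
def benchmark_cohort():
    """The recovery benchmark: n=300, 100 ROIs (4950 edges),
    planted strengths (0.6, 0.4) with 10-edge / 4-domain supports."""
    return generate_cohort(
        GeneratorConfig(n_participants=300, n_rois=100, seed=11)
    )
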