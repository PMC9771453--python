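import numpy as np
import pytest

from cogmaturity import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Deterministic 12-participant cohort, no dropout/missingness."""
    cfg = CohortConfig(
        n_participants=12,
        dropout_rate_per_wave=0.0,
        indicator_missing_rate=0.0,
        lie_gt6_rate=0.0,
        seed=20260,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_bundle():
    """Mid-size cohort with dropout, missingness and Lie-scale plants."""
    cfg = CohortConfig(n_participants=40, seed=77)
    return generate_cohort(cfg)
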