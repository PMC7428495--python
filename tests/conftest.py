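import numpy as np
import pytest

import connrep as cr


@pytest.fixture(scope="session")
def small_cohort():
    """Ten clean runs (5 subjects x 2 sessions), moderately contaminated."""
    spec = cr.CohortSpec(
        n_subjects=5, n_parcels=40, n_modules=4, seed=11,
        motion_spike_prob=0.0,
    )
    records, truth = cr.generate_cohort(spec)
    return spec, records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
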