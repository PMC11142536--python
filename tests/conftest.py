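import numpy as np
import pytest

from melafuse import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small paired-modality cohort shared across read-only tests."""
    cfg = CohortConfig(n_patients=8, spots_per_patient_mean=4, n_axis_bins=200,
                       n_signal_peaks=4, patch_px=32, seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
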