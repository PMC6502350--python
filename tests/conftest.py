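import numpy as np
import pytest

from cvrfn import (
    CohortConfig,
    ProtocolSpec,
    SubjectSpec,
    default_region_truth,
    make_analysis_mask,
    make_phantom,
)

SMALL_GRID = (12, 12, 6)


@pytest.fixture(scope="session")
def protocol():
    return ProtocolSpec()


@pytest.fixture(scope="session")
def truth():
    return default_region_truth()


@pytest.fixture
def noise_free_spec():
    return SubjectSpec(noise_sd_pct=0.0, drift_amplitude_pct=0.0, seed=11)


@pytest.fixture
def small_phantom(noise_free_spec):
    return make_phantom(noise_free_spec, SMALL_GRID)


@pytest.fixture
def small_mask(small_phantom):
    return make_analysis_mask(small_phantom.gm_prob, small_phantom.wm_prob, 0.8)


@pytest.fixture(scope="session")
def cohort_report():
    """Default 17-subject cohort, analysed once and shared by the
    recovery tests (both CO2 conditions, CVR and task stages)."""
    from cvrfn.pipeline import run_cohort

    config = CohortConfig(master_seed=1)
    return run_cohort(config)
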