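import numpy as np
import pandas as pd
import pytest

from mechanosep import generate_cohort, synthesize_traces, extract_events
from mechanosep.config import (
    AcquisitionParams,
    CohortSpec,
    healthy_spec,
    high_acuity_spec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_high_acuity():
    """Down-scaled high-acuity cohort: 60 subjects, 300 cells each."""
    spec = high_acuity_spec(n_cells_per_subject=300, seed=7)
    spec.n_subjects, spec.n_septic = 60, 14
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_healthy():
    spec = healthy_spec(n_cells_per_subject=300, seed=8)
    spec.n_subjects = 20
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noisefree_acq():
    return AcquisitionParams(descriptor_noise_sd_um=0.0)


@pytest.fixture(scope="session")
def default_acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def small_events(small_high_acuity, default_acq):
    """Events extracted end-to-end from the small high-acuity cohort."""
    subjects, cells = small_high_acuity
    batch = synthesize_traces(cells, default_acq, np.random.default_rng(99))
    events = extract_events(batch)
    truth = cells.set_index("cell_id")["true_type"]
    return events.assign(true_type=events["cell_id"].map(truth))
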