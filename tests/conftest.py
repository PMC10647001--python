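import numpy as np
import pandas as pd
import pytest

from als_proteome_state.containers import AbundanceMatrix
from als_proteome_state.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort: 4 fast / 4 slow patients, 3 visits,
    80 proteins of which 10 carry a log2 shift of 2."""
    spec = CohortSpec(
        n_fast=4,
        n_slow=4,
        visits_per_patient=(3, 3),
        n_proteins=80,
        n_signal_proteins=10,
        group_effect_log2=2.0,
        within_patient_sd_fast=0.4,
        within_patient_sd_slow=0.2,
        patient_random_effect_sd=0.2,
        batch_count=2,
        batch_effect_sd=0.3,
        missing_rate=0.05,
        seed=11,
    )
    matrix, metadata = generate_cohort(spec)
    return spec, matrix, metadata


@pytest.fixture()
def tiny_matrix():
    """Hand-sized complete matrix: 4 proteins x 6 samples."""
    rng = np.random.default_rng(5)
    values = pd.DataFrame(
        rng.normal(20, 1, size=(4, 6)),
        index=[f"P{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(6)],
    )
    return AbundanceMatrix(values=values, scale="log2")
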