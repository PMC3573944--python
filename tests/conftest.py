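import numpy as np
import pandas as pd
import pytest

from grsrisk import presets
from grsrisk.grs import score_cohort
from grsrisk.synth import simulate_cohort
from grsrisk.types import Cohort


def build_cohort(dosages, status=None, smoking=None, snp_ids=None):
    """Assemble a small Cohort from a dosage matrix (NaN = missing)."""
    dosages = np.asarray(dosages, dtype=float)
    n, k = dosages.shape
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(k)]
    if status is None:
        status = np.zeros(n, dtype=int)
    if smoking is None:
        smoking = np.zeros(n, dtype=int)
    return Cohort(
        subject_id=[f"s{i}" for i in range(n)],
        status=np.asarray(status),
        smoking=np.asarray(smoking),
        dosages=pd.DataFrame(dosages, columns=snp_ids),
    )


@pytest.fixture
def cohort_factory():
    return build_cohort


@pytest.fixture(scope="session")
def panel():
    return presets.DEFAULT_PANEL


@pytest.fixture(scope="session")
def sim_cohort():
    """One full-scale default cohort shared by the slower tests."""
    return simulate_cohort(presets.default_sim_config(seed=1))


@pytest.fixture(scope="session")
def sim_scores(sim_cohort):
    return score_cohort(sim_cohort, presets.DEFAULT_PANEL)
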