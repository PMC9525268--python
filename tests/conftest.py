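import numpy as np
import pytest

from slepredict.cohort import CohortConfig, PatientRecord, generate_cohort
from slepredict.preprocess import preprocess_cohort


@pytest.fixture(scope="session")
def small_cfg() -> CohortConfig:
    return CohortConfig(n_patients=40, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_series(small_cfg, small_cohort):
    return preprocess_cohort(small_cohort, feature_kinds=small_cfg.feature_kinds())


def make_record(
    visits,
    obs_months=36.0,
    followup_months=12.0,
    events=(),
    n_demo=5,
    patient_id="P0001",
):
    """Hand-built patient record for precise aggregation/labeling tests."""
    return PatientRecord(
        patient_id=patient_id,
        demographics=np.zeros(n_demo),
        visits=[(float(t), np.asarray(v, dtype=float)) for t, v in visits],
        events=list(events),
        obs_months=obs_months,
        followup_months=followup_months,
    )
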