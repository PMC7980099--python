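import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def tiny_patients() -> pd.DataFrame:
    """Three-patient table exercising all comorbidity-data states."""
    return pd.DataFrame(
        {
            "patient_id": ["A", "B", "C"],
            "age_years": [40.0, 70.0, 55.0],
            "sex": ["Male", "Female", "Male"],
            "race": ["White", "Black", "White"],
            "ethnicity": ["Hispanic", "Non-Hispanic", "Non-Hispanic"],
            "language": ["English", "Spanish", "English"],
            "income_band": ["<25k", "25-<50k", "50-<75k"],
            "insurer": ["Commercial", "Medicare/Medicaid", "None"],
            "hospital": ["tertiary", "tertiary", "quaternary"],
            "covid_unit": [True, False, True],
            "comorbidities": ["none", "moderate_dementia;severe_dementia", np.nan],
            "short_term_recovery_comorbidity": [False, True, False],
            "essential_function": [False, False, True],
        }
    )


@pytest.fixture()
def tiny_days() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": ["A", "A", "A", "B", "B", "C"],
            "date": [
                "2020-06-01", "2020-06-02", "2020-06-03",
                "2020-06-01", "2020-06-02", "2020-06-01",
            ],
            "sofa_score": [3.0, np.nan, 7.0, 10.0, 12.0, 5.0],
        }
    )


@pytest.fixture(scope="session")
def null_cohort():
    """A mid-sized synthetic cohort with no injected disparity."""
    from csctriage import emulate_study_profile, generate

    return generate(emulate_study_profile(n_patients=600, seed=11))
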