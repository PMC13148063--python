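import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Complete-data cases-only cohort, 2,000 subjects, fixed seed."""
    from cvriskval.synthetic_data import (default_covariate_model,
                                          generate_profiles)
    model = default_covariate_model().without_missingness()
    cohort, complete = generate_profiles(model, 2000, 0, seed=7)
    return cohort


@pytest.fixture(scope="session")
def small_cohort_risks(small_cohort):
    """(cohort, capped PREVENT overall-CVD risks) on the eligible subset."""
    from cvriskval.pipeline import compute_risk
    from cvriskval.risk_models import load_model, screen_validity
    risks, _ = compute_risk(small_cohort, "PREVENT", "overall_cvd")
    spec = load_model("PREVENT", "overall_cvd", "female")
    ok, _ = screen_validity(small_cohort, spec)
    m = ok.to_numpy() & risks.notna().to_numpy()
    return (small_cohort[m].reset_index(drop=True),
            np.minimum(risks.to_numpy()[m], 0.40))


@pytest.fixture()
def complete_profile_frame():
    """One fully specified female profile as a DataFrame row."""
    return pd.DataFrame([{
        "age": 50.0, "sex": "female", "race": "white",
        "systolic_bp": 160.0, "diastolic_bp": 85.0,
        "total_chol": 200.0, "hdl": 45.0, "ldl": 120.0, "bmi": 35.0,
        "egfr": 90.0, "diabetes": 0.0, "current_smoker": 1.0,
        "antihypertensive_use": 1.0, "lipid_lowering_use": 0.0,
        "aspirin_use": 0.0, "hba1c": 7.5, "adi_percentile": 50.0,
    }])
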