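import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort_tables():
    """One small synthetic study shared by integration-style tests."""
    from preptraj.synthetic_cohort import CohortConfig, generate_dataset

    config = CohortConfig(n_subjects=250, seed=424242)
    return config, generate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def two_cluster_series():
    """Longitudinal series with two well-separated constant groups (0 / 20)."""
    gen = np.random.default_rng(7)
    months = [0, 1, 3, 6, 9, 12]
    rows = []
    for sid in range(200):
        level = 0.0 if sid < 100 else 20.0
        for m in months:
            rows.append({"subject_id": sid, "visit_month": m,
                         "value": level + gen.normal(0, 0.5)})
    return pd.DataFrame(rows)
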