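import numpy as np
import pytest

from actipred import (
    CohortConfig,
    build_feature_table,
    generate_clustered_cohort,
    generate_cohort,
    two_archetype_configs,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Four patients with one-to-two-week stays; fast enough for most tests."""
    cfg = CohortConfig(
        n_patients=4, los_min=6, los_max=14, los_log_mean=np.log(9),
        los_log_sd=0.3, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return build_feature_table(small_cohort)


@pytest.fixture(scope="session")
def clustered_features():
    cohort = generate_clustered_cohort(two_archetype_configs(), seed=5)
    table = build_feature_table(cohort)
    truth = {p.patient_id: p for p in cohort.patients}
    return table, truth
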