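import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def longitudinal_subjects():
    from cagmosaic import load_cohort_fixture

    return load_cohort_fixture("longitudinal")


@pytest.fixture(scope="session")
def longitudinal_table():
    from cagmosaic import load_cohort_table

    return load_cohort_table("longitudinal")


@pytest.fixture(scope="session")
def longitudinal_fits(longitudinal_subjects):
    from cagmosaic import cohort_trajectories

    return cohort_trajectories(longitudinal_subjects)
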