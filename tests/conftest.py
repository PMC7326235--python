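import pytest
from hypothesis import HealthCheck, settings

import rascore as rc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dev_period_tab():
    return rc.load_development_period_crosstab()


@pytest.fixture(scope="session")
def dev_age_tab():
    return rc.load_development_age_crosstab()


@pytest.fixture(scope="session")
def dev_model(dev_period_tab, dev_age_tab):
    """The development model built from the packaged cross-tabulations."""
    return rc.ReproductiveAgeingScore.from_crosstabs(dev_period_tab, dev_age_tab)


@pytest.fixture(scope="session")
def dev_fit(dev_model):
    """Both membership curves refitted to the development series."""
    return dev_model.fit()


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (n=5000, seed 0)."""
    return rc.generate_cohort(rc.SyntheticCohortConfig())


@pytest.fixture(scope="session")
def eligible_cohort(default_cohort):
    kept, _ = rc.apply_eligibility_filters(default_cohort)
    return kept


def make_record(**overrides):
    """A well-formed eligible record with sensible defaults."""
    base = dict(
        id="r0",
        age=50,
        periods_last_12m=12,
        regularity=rc.Regularity.REGULAR,
    )
    base.update(overrides)
    return rc.ParticipantRecord(**base)
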