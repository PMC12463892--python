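import pytest
from hypothesis import HealthCheck, settings

import ckdsim as ck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> ck.TransitionParameters:
    return ck.TransitionParameters()


@pytest.fixture(scope="session")
def combined_strategy() -> ck.Strategy:
    return ck.get_strategy("hypertension_diabetes_age65")


@pytest.fixture(scope="session")
def small_cohort() -> list[ck.Individual]:
    """2,000-member default-mixture cohort, frozen seed."""
    return ck.synthesize_cohort(ck.PopulationSpec(n=2000, seed=3))


def make_individual(
    id=0,
    age=70,
    hypertension=True,
    diabetes=False,
    state=ck.State.AT_RISK,
    stage="NONE",
) -> ck.Individual:
    return ck.Individual(
        id=id,
        age=age,
        hypertension=hypertension,
        diabetes=diabetes,
        state=state,
        stage_at_entry=stage,
    )
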