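import pytest

from scorerisk import CohortSpec, build_model, generate


@pytest.fixture(scope="session")
def low_risk_model():
    return build_model("low_risk")


@pytest.fixture(scope="session")
def high_risk_model():
    return build_model("high_risk")


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort at the study's default conditions."""
    cohort, _ = generate(CohortSpec(seed=20100))
    return cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient cohort for fast end-to-end plumbing tests."""
    cohort, _ = generate(CohortSpec(n=40, seed=7))
    return cohort
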