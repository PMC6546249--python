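import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ranbias import BiasSpec, StudyDesign

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230601)


@pytest.fixture(scope="session")
def case_study_design():
    """AML maintenance-chemotherapy study under the null hypothesis."""
    return StudyDesign(
        n=64,
        accrual_length=18.0,
        total_length=52.0,
        alpha=0.05,
        dropout_rate=0.0077,
        baseline_hazard=0.0431,
        log_hazard_ratio=0.0,
    )


@pytest.fixture(scope="session")
def case_study_bias():
    """Strong selection bias plus a small improving logarithmic trend."""
    return BiasSpec(eta=0.1831, theta=-0.1144, trend="logarithmic")


@pytest.fixture(scope="session")
def sensitivity_design():
    """Common design of the sensitivity scenarios (null, n=40 variant)."""
    return StudyDesign(
        n=40,
        accrual_length=30.0,
        total_length=90.0,
        alpha=0.05,
        dropout_rate=0.02,
        baseline_hazard=0.06,
        log_hazard_ratio=0.0,
    )
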