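import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from aaimpact import (
    BetaParams,
    SurrogateLinkage,
    ToxicityStructure,
    TherapeuticOutcomeDistribution,
    example_config,
    example_value_tables,
)


@pytest.fixture
def post_p():
    """Surrogate-response posterior after 15/50 responders on a Beta(1,9) prior."""
    return BetaParams(16, 44)


@pytest.fixture
def post_q():
    """Severe-toxicity posterior after 0/50 events on a Beta(2,8) prior."""
    return BetaParams(2, 58)


@pytest.fixture
def linkage():
    return SurrogateLinkage(p_cb_given_se=0.7, p_cb_given_nose=0.05)


@pytest.fixture
def structure():
    return ToxicityStructure(p_t1_fixed=0.0, split=(0.5, 0.5))


@pytest.fixture
def tables():
    return example_value_tables()


@pytest.fixture
def simple_dist():
    """A hand-checkable outcome distribution: (0, 0.1, 0.1, 0, 0.4, 0.4)."""
    return TherapeuticOutcomeDistribution((0.0, 0.1, 0.1, 0.0, 0.4, 0.4))


@pytest.fixture
def config():
    return example_config()
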