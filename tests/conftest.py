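import numpy as np
import pytest

from bmams import DesignSpec, PriorSpec, Scenario
from bmams import case_study as cs


@pytest.fixture(scope="session")
def design3x2():
    """Case-study geometry: 3 arms, 2 stages, interim at 50%, sigma 340."""
    return cs.design_spec(102)


@pytest.fixture(scope="session")
def prior_vague():
    """Uninformative case-study prior (all precisions 1e-6)."""
    return cs.prior_spec("U")


@pytest.fixture(scope="session")
def variant_u():
    return cs.variant("U")


@pytest.fixture(scope="session")
def variant_c():
    return cs.variant("C")


@pytest.fixture(scope="session")
def global_null():
    return cs.global_null()


@pytest.fixture(scope="session")
def alt_scenario():
    return Scenario.from_effects(cs.MU0_CTRL, cs.THETA_ALT)
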