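import dataclasses

import pytest

from bonebridge import CohortSpec, RiskModelParams, TrajectoryCoefficients, generate_cohort
from bonebridge.risk import _default_hip, _default_mof


@pytest.fixture(scope="session")
def coeffs():
    return TrajectoryCoefficients()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort for pipeline property tests."""
    return generate_cohort(CohortSpec(n=400, seed=7))


@pytest.fixture(scope="session")
def default_params():
    return RiskModelParams()


@pytest.fixture()
def constant_hazard_params():
    """Flat hazards, no mortality: closed-form 10-year risk 1 - exp(-10c)."""
    hip = dataclasses.replace(_default_hip(), gompertz_a=0.003, gompertz_b=0.0)
    mof = dataclasses.replace(_default_mof(), gompertz_a=0.01, gompertz_b=0.0)
    return RiskModelParams(hip=hip, mof=mof, mortality_a=0.0, mortality_b=0.0)
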