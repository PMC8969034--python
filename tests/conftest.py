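import pytest
from hypothesis import settings

from mscca import (
    SyntheticConfig,
    builtin_scenarios,
    generate_parameter_set,
    generate_worked_fixture,
    run_scenario,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked():
    """Tiny hand-written parameter set confined to EDSS 0-2 plus death."""
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def default_params():
    return generate_parameter_set(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def dmf_scenarios():
    return builtin_scenarios("DMF")


@pytest.fixture(scope="session")
def dmf_traces(default_params, dmf_scenarios):
    """Traces of the four built-in scenarios on the default synthetic set."""
    return {s.label: run_scenario(default_params, s) for s in dmf_scenarios}


@pytest.fixture()
def zero_mortality_worked(worked):
    """Worked fixture with background mortality switched off."""
    ps = worked.copy()
    ps.mortality.death_prob[:] = 0.0
    ps.mortality.death_prob[-1] = 1.0  # keep the table closed
    return ps
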