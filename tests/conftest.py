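import pytest

from slpathway import bundled_parameters, solve_steady_state


@pytest.fixture(scope="session")
def ab_params():
    return bundled_parameters("ab_adjusted")


@pytest.fixture(scope="session")
def ac_params():
    return bundled_parameters("ac_adjusted")


@pytest.fixture(scope="session")
def ab_steady(ab_params):
    return solve_steady_state(ab_params)


@pytest.fixture(scope="session")
def ac_steady(ac_params):
    return solve_steady_state(ac_params)
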