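import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

from saltckd import generate_bundle, run_scenario
from saltckd.disease import derive_case_fatality
from saltckd.exposure import builtin_scenarios


@pytest.fixture(scope="session")
def bundle():
    return generate_bundle(seed=1, realism="smooth")


@pytest.fixture(scope="session")
def noisy_bundle():
    return generate_bundle(seed=1, realism="noisy")


@pytest.fixture(scope="session")
def case_fatality(bundle):
    return derive_case_fatality(bundle, "ode_consistent")


@pytest.fixture(scope="session")
def all_results(bundle, case_fatality):
    """Deterministic runs of all six built-in scenarios (PSA off)."""
    return {
        s.name: run_scenario(bundle, s, case_fatality=case_fatality)
        for s in builtin_scenarios()
    }
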