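"""Shared fixtures: the expensive solves are done once per session."""

import pytest

from rtenergy import ParameterSet, find_steady_state, reference_state
from rtenergy.scenarios import reduced_model_experiment
from rtenergy.sensitivity import response_coefficients


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def ref_state():
    return reference_state()


@pytest.fixture(scope="session")
def ref_ss(params, ref_state):
    ss = find_steady_state(params, ref_state)
    assert ss.converged
    return ss


@pytest.fixture(scope="session")
def reduced_result(params, ref_ss):
    return reduced_model_experiment(params, ref_ss=ref_ss)


@pytest.fixture(scope="session")
def response_report(params, ref_ss):
    return response_coefficients(params, ref_ss)
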