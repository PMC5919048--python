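"""Shared fixtures: coarse meshes and solutions reused across solver tests."""

import warnings

import numpy as np
import pytest

from irepf import (
    SimulationDomain,
    build_mesh,
    cervical_cancer_params,
    pulse_count_family,
    solve_potential,
)
from irepf.errors import ExtrapolationWarning


@pytest.fixture(autouse=True)
def _quiet_extrapolation():
    # Case-study protocols use n = 90, beyond the calibrated 1..60 range; the
    # warning is intentional but noisy in bulk runs.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        yield


@pytest.fixture(scope="session")
def domain_1kv():
    return SimulationDomain(applied_voltage_v=1000.0)


@pytest.fixture(scope="session")
def coarse_mesh(domain_1kv):
    return build_mesh(domain_1kv, 0.8)


@pytest.fixture(scope="session")
def linear_solution(coarse_mesh):
    """Constant-conductivity solve (linear problem) on the coarse mesh."""
    return solve_potential(coarse_mesh, 1000.0, 0.23)


@pytest.fixture(scope="session")
def nonlinear_solution(coarse_mesh):
    """Gompertz-conductivity Picard solve on the coarse mesh."""
    return solve_potential(coarse_mesh, 1000.0, cervical_cancer_params(100.0))


@pytest.fixture(scope="session")
def family_100us():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pulse_count_family(100.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180425)
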