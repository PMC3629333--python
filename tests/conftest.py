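"""Shared fixtures for the sparsefmri test suite."""

import pytest

from sparsefmri import (
    AcquisitionDesign,
    StimulationPlan,
    calibrate,
    make_canonical_hrf,
)


@pytest.fixture(scope="session")
def kernel():
    """Calibrated canonical HRF at the standard 100 ms resolution."""
    return calibrate(make_canonical_hrf(0.1))


@pytest.fixture
def design_12():
    return AcquisitionDesign(TR=12)


@pytest.fixture
def design_8():
    return AcquisitionDesign(TR=8)


@pytest.fixture
def design_4():
    return AcquisitionDesign(TR=4)


@pytest.fixture
def plan_4():
    return StimulationPlan(ISI=4)


@pytest.fixture
def plan_8():
    return StimulationPlan(ISI=8)
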