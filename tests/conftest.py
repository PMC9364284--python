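"""Shared fixtures: the study's two reference designs, sized once per session."""

import numpy as np
import pytest

from mamsim import (
    BinaryEndpointModel,
    DesignSpec,
    find_critical_constant,
    obf_boundaries,
)


@pytest.fixture(scope="session")
def spec_rct() -> DesignSpec:
    """Single-stage four-arms-plus-control design at the study's error rates."""
    return DesignSpec(K=4, J=1)


@pytest.fixture(scope="session")
def spec_mams() -> DesignSpec:
    """Three-stage four-arms-plus-control design at the study's error rates."""
    return DesignSpec(K=4, J=3)


@pytest.fixture(scope="session")
def bounds_rct(spec_rct):
    return obf_boundaries(1, find_critical_constant(spec_rct))


@pytest.fixture(scope="session")
def bounds_mams(spec_mams):
    return obf_boundaries(3, find_critical_constant(spec_mams))


@pytest.fixture(scope="session")
def model_33() -> BinaryEndpointModel:
    """The budget-table scenario: 30% baseline success, 30-point effect."""
    return BinaryEndpointModel(0.3, 0.3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_901)
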