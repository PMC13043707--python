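import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from corneaionto.bioheat import solve_protocol
from corneaionto.config import (
    CALIBRATED_CONFIG_NAME,
    PROTOCOL_CURRENTS_MA,
    default_stack,
    load_packaged_config,
)
from corneaionto.electro import CurrentProtocol


@pytest.fixture(scope="session")
def stack():
    """Published four-layer stack with the default disc area."""
    return default_stack()


@pytest.fixture(scope="session")
def calibrated():
    """Shipped reference-calibrated run configuration (single parameter set)."""
    return load_packaged_config(CALIBRATED_CONFIG_NAME)


@pytest.fixture(scope="session")
def calibrated_sweep(calibrated):
    """Solved fields for the nine protocol currents at 10/30/60 s."""
    fields = {}
    for i_mA in PROTOCOL_CURRENTS_MA:
        protocol = CurrentProtocol(i_mA, 60.0, (10.0, 30.0, 60.0))
        fields[i_mA] = solve_protocol(
            calibrated.stack, protocol, calibrated.solver, calibrated.boundary
        )
    return fields
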