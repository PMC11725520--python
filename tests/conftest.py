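import numpy as np
import pytest

import circamp as ca

MODELS = list(ca.registered_models())


@pytest.fixture(scope="session", params=MODELS)
def any_spec(request):
    """Each pacemaker model in turn."""
    return ca.get_model(request.param)


@pytest.fixture(scope="session")
def forger():
    return ca.get_model("forger99")


@pytest.fixture(scope="session")
def hannay():
    return ca.get_model("hannay19_sp")


@pytest.fixture(scope="session")
def bright_pulse():
    """The 1-h 8000-lux bright-light pulse protocol."""
    return ca.PulseProtocol(duration=1.0, intensity=8000.0)


@pytest.fixture(scope="session")
def arc_curves(bright_pulse):
    """PRC/ARC of the 1-h 8000-lux pulse for every model, 0.5-h grid."""
    return {name: ca.scan_response(ca.get_model(name), bright_pulse) for name in MODELS}


@pytest.fixture(scope="session")
def regular_14d():
    """14 days of 23:00-07:00 sleep at 1-min epochs."""
    return ca.regular_schedule(14, 23.0, 8.0, 1)
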