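import pytest

from thinfil import load_parameter_set


@pytest.fixture(scope="session")
def set1():
    """Steady-state (force-pCa) parameter set."""
    return load_parameter_set("set1")


@pytest.fixture(scope="session")
def set2():
    """Twitch-kinetics parameter set."""
    return load_parameter_set("set2")
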