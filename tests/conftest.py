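import pytest

from pcdcea import load_config
from pcdcea.decision import DO_NOTHING, PRESETS


@pytest.fixture(scope="session")
def params():
    """Shipped default parameter set (session-scoped; treat as read-only)."""
    return load_config()


@pytest.fixture(scope="session")
def best_values(params):
    return params.point_values()


@pytest.fixture(scope="session")
def all_strategies():
    return [DO_NOTHING] + list(PRESETS.values())
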