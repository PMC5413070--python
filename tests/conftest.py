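import pytest
from hypothesis import HealthCheck, settings as hsettings

hsettings.register_profile(
    "suite", max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
hsettings.load_profile("suite")

from egctools import attach_default, make_fixture, normalize_model  # noqa: E402

_CACHE: dict = {}


def prepared_fixture(name):
    """Normalized fixture model with dissipation reactions attached (copy)."""
    if name not in _CACHE:
        model, spec = make_fixture(name)
        model, _ = normalize_model(model)
        _CACHE[name] = (attach_default(model), spec)
    attached, spec = _CACHE[name]
    return attached.copy(), spec


@pytest.fixture
def prepared():
    return prepared_fixture
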