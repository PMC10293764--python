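import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def smx_bounds():
    """Subscript bounds for protonated sulfamethoxazole (C10H11N3O3S + H)."""
    from fragnets import SubscriptBounds

    return SubscriptBounds.from_dict({"C": 10, "S": 1, "O": 3, "N": 3, "H": 12})


@pytest.fixture
def chno_bounds():
    """Small CHNO-only bounds (heavy isotopes disabled) for oracle tests."""
    from fragnets import SubscriptBounds

    return SubscriptBounds.from_dict(
        {"C": 6, "H": 6, "N": 6, "O": 6, "13C": 0, "34S": 0})
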