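import pytest
from hypothesis import HealthCheck, settings

from gliosyn import AstroParams, SynapseParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def syn_depressing() -> SynapseParams:
    """Depressing synapse: plateau release 0.5, U0 above threshold."""
    return SynapseParams(omega_d=2.0, omega_f=3.3, u0_star=0.5)


@pytest.fixture
def syn_facilitating() -> SynapseParams:
    """Facilitating synapse: bimodal frequency response peaking near 2.8 Hz."""
    return SynapseParams(omega_d=2.0, omega_f=2.0, u0_star=0.15)


@pytest.fixture
def astro_decreasing() -> AstroParams:
    """Release-decreasing astrocyte (alpha = 0)."""
    return AstroParams(alpha=0.0)


@pytest.fixture
def astro_increasing() -> AstroParams:
    """Release-increasing astrocyte (alpha = 1)."""
    return AstroParams(alpha=1.0)
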