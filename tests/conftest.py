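import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from repliscan import SimConfig, progressive_align, simulate_panel


@pytest.fixture(scope="session")
def default_panel():
    """One default-condition synthetic panel shared across the session."""
    return simulate_panel(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_alignment(default_panel):
    panel, _ = default_panel
    return progressive_align(panel.targets)
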