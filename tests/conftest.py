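import pytest
from hypothesis import HealthCheck, settings

from stillmetrics import SynthConfig, generate_panel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel_and_truth():
    """Default two-tier synthetic panel (both years) with its ground truth."""
    return generate_panel(SynthConfig(n_countries=30, seed=2025))


@pytest.fixture(scope="session")
def panel(panel_and_truth):
    return panel_and_truth[0]


@pytest.fixture(scope="session")
def panel_2015(panel):
    return [r for r in panel if r.year == 2015]
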