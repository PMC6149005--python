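import pytest

from lncforge.simulate import GeneratorConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (mild predictor noise)."""
    return simulate_study(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def clean_study():
    """Noise-free study: consensus vote must recover truth exactly."""
    return simulate_study(GeneratorConfig(seed=12, predictor_noise=0.0))
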