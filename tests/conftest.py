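import hypothesis
import pytest

from dietheart import FHSGeneratorConfig, MCEGeneratorConfig, generate_fhs, generate_mce

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def mce_default():
    """Default-configuration trial cohort at a fixed seed."""
    return generate_mce(MCEGeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def fhs_default():
    """Default-configuration observational cohort at a fixed seed."""
    return generate_fhs(FHSGeneratorConfig(seed=1))


@pytest.fixture
def small_mce():
    """A fast, small trial cohort for plumbing tests."""
    return generate_mce(MCEGeneratorConfig(n_diet=60, n_control=55, seed=3))
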