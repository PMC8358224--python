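import pytest

from cytc6 import GeneratorConfig, SequenceGenerator


@pytest.fixture(scope="session")
def clean_generator() -> SequenceGenerator:
    """Noise-free generator: planted features are exactly recoverable."""
    return SequenceGenerator(GeneratorConfig(seed=77, substitution_noise=0.0))


@pytest.fixture(scope="session")
def noisy_generator() -> SequenceGenerator:
    """Generator at the default 2% substitution noise."""
    return SequenceGenerator(GeneratorConfig(seed=101))


@pytest.fixture(scope="session")
def refs(clean_generator):
    return clean_generator.reference_profile
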