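import pytest

from costim.config import GeneratorConfig
from costim.synthetic import generate_study


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    """2 subjects x 2 blocks: smallest study that exercises both types."""
    return GeneratorConfig(n_subjects=2, n_blocks=2, seed=11)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return generate_study(tiny_config)


@pytest.fixture(scope="session")
def noiseless_config() -> GeneratorConfig:
    """Deterministic steady vectors: no sample noise, no direction jitter."""
    return GeneratorConfig(n_subjects=3, n_blocks=2, noise_sd=0.0,
                           within_subject_dir_sd=0.0, seed=5)


@pytest.fixture(scope="session")
def noiseless_study(noiseless_config):
    return generate_study(noiseless_config)
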