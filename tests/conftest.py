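import numpy as np
import pytest

from petriage.synthetic import GeneratorConfig, build_atlas, generate_cohort


@pytest.fixture(scope="session")
def atlas32():
    return build_atlas(32)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def cohort2000():
    """A default-parameter cohort large enough for calibration checks."""
    return generate_cohort(GeneratorConfig(n_samples=2000, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
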