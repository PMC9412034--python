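import numpy as np
import pytest
from hypothesis import settings

from otva.synthetic_ecg import (
    GeneratorConfig,
    generate_clinical_like,
    generate_database,
)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_anatomies=4, n_electrode_configs=3, seed=3)


@pytest.fixture(scope="session")
def small_db(small_config):
    """Reduced factorial database: 4 x 12 x 3 = 144 noise-free beats."""
    return generate_database(small_config)


@pytest.fixture(scope="session")
def default_db():
    """Full default factorial database (16 x 12 x 13 = 2,496 beats)."""
    return generate_database(GeneratorConfig())


@pytest.fixture(scope="session")
def clinical_small():
    cfg = GeneratorConfig(n_anatomies=4, n_electrode_configs=3, seed=17,
                          noise_sd=0.05)
    return generate_clinical_like(60, 0.3, cfg)


@pytest.fixture(scope="session")
def segments(small_db):
    from otva.preprocess import BeatPreprocessor

    return BeatPreprocessor().fit_transform(small_db.records[:40])
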