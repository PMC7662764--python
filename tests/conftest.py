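import numpy as np
import pytest

from tennisgcn import (
    GeneratorConfig,
    canonical_graph,
    generate_dataset,
)


@pytest.fixture(scope="session")
def graph():
    return canonical_graph()


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, outlier-free generator: classes are separable by construction."""
    return GeneratorConfig(
        class_counts=(30, 30, 30),
        noise_sd=0.0,
        outlier_frac=0.0,
        subject_sd=0.0,
        stroke_var=0.0,
        left_handed_frac=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return generate_dataset(clean_config)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Small noisy dataset for pipeline tests (not the benchmark conditions)."""
    return generate_dataset(
        GeneratorConfig(class_counts=(20, 20, 20), noise_sd=0.1, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
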