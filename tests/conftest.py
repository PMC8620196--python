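import numpy as np
import pytest

from lncpi import PipelineConfig, SyntheticSpec, generate_dataset
from lncpi.classifiers import ClassifierConfig, DNNConfig


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale world small enough for repeated full-pipeline runs."""
    return SyntheticSpec(
        n_lnc=24, n_prot=12, lnc_len=120, prot_len=60, noise_rate=0.05, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced selection size / folds so pipeline tests stay fast."""
    return PipelineConfig(
        classifier=ClassifierConfig(dnn=DNNConfig(epochs=30)),
        k_features=15,
        n_folds=3,
        n_repeats=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
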