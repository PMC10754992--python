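import numpy as np
import pytest

import stndetect as sd


@pytest.fixture(scope="session")
def pheno_params():
    return sd.PhenoParams()


@pytest.fixture(scope="session")
def small_dataset(pheno_params):
    """600 samples (300 per class) at generator defaults."""
    return sd.generate_dataset(pheno_params, 30, 10, 2500.0, seed=42)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return sd.split_dataset(small_dataset, 0.75, stratified=True, seed=7)


@pytest.fixture(scope="session")
def trained_snn(small_split):
    """A quickly trained quarter-width feedforward detector."""
    tr, va = small_split
    spec = sd.build_detector("snn7", width_scale=0.25)
    return sd.train(spec, tr, va, sd.TrainConfig(epochs=8, seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
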