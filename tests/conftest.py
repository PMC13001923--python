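import numpy as np
import pytest

from graphomics import SyntheticSpec, generate_multiomics


@pytest.fixture(scope="session")
def small_dataset():
    """40-sample 2-class dataset with three small views; quick to train on."""
    spec = SyntheticSpec(
        n_samples=40,
        n_classes=2,
        views=(("mrna", 20), ("meth", 20), ("mirna", 10)),
        noise_sd=0.05,
        seed=7,
    )
    return generate_multiomics(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
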