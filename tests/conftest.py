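import numpy as np
import pytest

from neuroage import ModelSpec, PhantomParams, TrainConfig, generate_cohort, train
from neuroage.training import stratified_split


@pytest.fixture(scope="session")
def small_params():
    return PhantomParams(grid_shape=(16, 16, 16), noise_sd=0.02, seed=7)


@pytest.fixture(scope="session")
def noiseless_params():
    return PhantomParams(grid_shape=(16, 16, 16), noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(small_params):
    """12 subjects at 16^3 — enough for wiring tests, fast to build."""
    return generate_cohort(12, 20, 80, 0.5, small_params, seed=3)


@pytest.fixture(scope="session")
def tiny_spec():
    return ModelSpec(variant="cnn_mlp", input_shape=(16, 16, 16), n_conv_blocks=2)


@pytest.fixture(scope="session")
def tiny_trained(tiny_cohort, tiny_spec):
    """A briefly trained model shared by inference-side tests."""
    cfg = TrainConfig(
        optimizer="adam", learning_rate=1e-3, decay=0.0003,
        batch_size=4, epochs=3, seed=5,
    )
    model, history = train(tiny_spec, tiny_cohort, cfg)
    return model, history


def rng(seed=0):
    return np.random.default_rng(seed)
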