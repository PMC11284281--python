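import numpy as np
import pytest

import tumorkit as tk
from tumorkit.model import ModelConfig, build_classifier, train


@pytest.fixture(scope="session")
def default_trained_models():
    """Classifiers trained on 200-per-class default phantoms, three seeds.

    Shared across the training-accuracy and saliency-localization tests
    because each training run is the expensive step of the suite.
    """
    models = []
    for seed in (0, 1, 2):
        ds = tk.generate_dataset(200, tk.PhantomConfig(), seed=seed)
        cfg = ModelConfig(epochs=30, learning_rate=0.001, seed=seed)
        models.append(train(build_classifier(cfg), ds))
    return models


@pytest.fixture(scope="session")
def noise_free_trained_model():
    """Classifier trained on a small noise-free, perfectly separable set."""
    cfg = tk.PhantomConfig(noise_sigma=0.0, tumor_texture_sigma=0.0,
                           background_texture_sigma=0.0)
    ds = tk.generate_dataset(30, cfg, seed=5)
    model = train(build_classifier(ModelConfig(epochs=30, seed=5)), ds)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
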